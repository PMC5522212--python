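"""cis classification against a brute-force oracle; Smith-Waterman against a
naive DP recomputation and an independent aligner; trans hit logic."""
import numpy as np
import pandas as pd
import pytest

from lncarray.targets import (
    TargetPredConfig,
    classify_cis,
    local_align,
    predict_targets,
    predict_trans,
)
from tests.conftest import make_transcript

# ---------------------------------------------------------------------------
# brute-force cis oracle: re-implements the precedence rules naively with
# per-base position sets instead of interval arithmetic
# ---------------------------------------------------------------------------

def brute_force_cis(lnc, gene, config):
    if lnc.chrom != gene.chrom:
        return "none"
    lnc_span = set(range(lnc.start, lnc.end))
    gene_span = set(range(gene.start, gene.end))
    lnc_exonic = set().union(*(range(s, e) for s, e in lnc.exons))
    gene_exonic = set().union(*(range(s, e) for s, e in gene.exons))
    same = lnc.strand == gene.strand
    if same and (lnc_exonic & gene_exonic):
        return "Sense"
    if not same and (lnc_span & gene_span):
        return "Antisense"
    introns = [set(range(s, e)) for s, e in gene.introns()]
    if any(lnc_span <= intron for intron in introns):
        return "Intronic"
    if lnc_span & gene_span:
        return "Intergenic10k"
    # gap = bases strictly between the spans
    if lnc.end <= gene.start:
        gap = gene.start - lnc.end
        left, right = lnc, gene
    else:
        gap = lnc.start - gene.end
        left, right = gene, lnc
    if not same and left.strand == "-" and right.strand == "+":
        if gap <= config.bidirectional_tss_gap:
            return "Bidirectional"
        if gap <= config.divergent_tss_gap:
            return "Divergent"
    if gap <= config.cis_window:
        return "Intergenic10k"
    return "none"


def random_geometry(rng):
    chrom = rng.choice(["chr1", "chr2"], p=[0.9, 0.1])
    g_start = int(rng.integers(0, 40_000))
    n_exons = int(rng.integers(1, 4))
    exons, pos = [], g_start
    for _ in range(n_exons):
        length = int(rng.integers(50, 600))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(100, 1_500))
    gene = make_transcript(
        probe_id="g", rna_type="mRNA", chrom="chr1",
        strand=str(rng.choice(["+", "-"])),
        start=exons[0][0], end=exons[-1][1], exons=exons,
    )
    l_start = int(rng.integers(0, 60_000))
    l_len = int(rng.integers(50, 2_000))
    lnc = make_transcript(
        probe_id="l", rna_type="lncRNA", chrom=str(chrom),
        strand=str(rng.choice(["+", "-"])),
        start=l_start, end=l_start + l_len,
    )
    return lnc, gene


class TestClassifyCis:
    config = TargetPredConfig()

    def test_sense_on_exact_exon_overlap(self):
        gene = make_transcript("g", "mRNA", strand="+", start=100, end=1000,
                               exons=[(100, 300), (600, 1000)])
        lnc = make_transcript("l", "lncRNA", strand="+", start=100, end=300)
        call = classify_cis(lnc, gene, self.config)
        assert call.label == "Sense" and call.distance == 0

    def test_antisense_on_opposite_strand_overlap(self):
        gene = make_transcript("g", "mRNA", strand="+", start=100, end=1000)
        lnc = make_transcript("l", "lncRNA", strand="-", start=900, end=1500)
        assert classify_cis(lnc, gene, self.config).label == "Antisense"

    def test_intronic_between_exons(self):
        gene = make_transcript("g", "mRNA", strand="+", start=100, end=400,
                               exons=[(100, 200), (300, 400)])
        lnc = make_transcript("l", "lncRNA", strand="+", start=220, end=280)
        assert classify_cis(lnc, gene, self.config).label == "Intronic"

    @pytest.mark.parametrize("gap, label", [
        (500, "Bidirectional"), (1000, "Bidirectional"),
        (3000, "Divergent"), (5000, "Divergent"), (7000, "Intergenic10k"),
    ])
    def test_head_to_head_split_by_tss_gap(self, gap, label):
        gene = make_transcript("g", "mRNA", strand="+", start=20_000, end=25_000)
        lnc = make_transcript("l", "lncRNA", strand="-",
                              start=20_000 - gap - 600, end=20_000 - gap)
        assert classify_cis(lnc, gene, self.config).label == label

    def test_window_boundary(self):
        gene = make_transcript("g", "mRNA", strand="+", start=50_000, end=55_000)
        near = make_transcript("l", "lncRNA", strand="+", start=39_401, end=40_001)
        far = make_transcript("l2", "lncRNA", strand="+", start=20_000, end=29_999)
        near_call = classify_cis(near, gene, self.config)
        assert near_call.label == "Intergenic10k" and near_call.distance == 9_999
        assert classify_cis(far, gene, self.config).label == "none"

    def test_different_chromosomes(self):
        gene = make_transcript("g", "mRNA", chrom="chr1", start=0, end=100)
        lnc = make_transcript("l", "lncRNA", chrom="chr2", start=0, end=100)
        call = classify_cis(lnc, gene, self.config)
        assert call.label == "none" and call.distance is None

    def test_agrees_with_brute_force_oracle_on_random_geometries(self):
        rng = np.random.default_rng(2024)
        mismatches = []
        for _ in range(3_000):
            lnc, gene = random_geometry(rng)
            fast = classify_cis(lnc, gene, self.config).label
            slow = brute_force_cis(lnc, gene, self.config)
            if fast != slow:
                mismatches.append((lnc, gene, fast, slow))
        assert not mismatches, mismatches[:3]


# ---------------------------------------------------------------------------
# Smith-Waterman oracles
# ---------------------------------------------------------------------------

def naive_sw_score(a, b, match=1, mismatch=-1, gap=-2):
    """Quadratic DP recomputation, scalar loops only."""
    n, m = len(a), len(b)
    h = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            h[i][j] = max(0, h[i - 1][j - 1] + s, h[i - 1][j] + gap, h[i][j - 1] + gap)
            best = max(best, h[i][j])
    return best


class TestLocalAlign:
    def test_identical_twenty_mers(self):
        seq = "ACGTACGTACGTACGTACGT"
        result = local_align(seq, seq)
        assert result.score == 20 and result.identity == 1.0
        assert result.a_span == (0, 20)

    def test_worked_example(self):
        result = local_align("ACGTACGT", "TTACGTAA")
        assert result.score == 5
        assert result.aligned_a == "ACGTA" and result.aligned_b == "ACGTA"

    def test_no_positive_cell(self):
        assert local_align("AAAA", "CCCC").score == 0

    def test_empty_sequence(self):
        result = local_align("", "ACGT")
        assert result.score == 0 and result.a_span is None

    def test_n_scores_as_mismatch(self):
        assert local_align("ANNA", "ANNA").score == naive_sw_score("ANNA", "ANNA")

    def test_score_matches_naive_dp_on_random_pairs(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            a = "".join(rng.choice(bases, size=rng.integers(1, 51)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 51)))
            assert local_align(a, b).score == naive_sw_score(a, b), (a, b)

    def test_score_matches_independent_aligner(self):
        """Cross-check against Biopython's local aligner on random pairs."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            a = "".join(rng.choice(bases, size=rng.integers(5, 40)))
            b = "".join(rng.choice(bases, size=rng.integers(5, 40)))
            expected = aligner.score(a, b)
            got = local_align(a, b).score
            assert got == (expected if expected > 0 else 0), (a, b)

    def test_symmetry_and_self_score(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(rng.choice(bases, size=rng.integers(1, 40)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 40)))
            assert local_align(a, b).score == local_align(b, a).score
            assert local_align(a, a).score == len(a)


class TestPredictTrans:
    def test_planted_22mer_detected(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        element = "".join(rng.choice(bases, 22))
        lnc = "".join(rng.choice(bases, 150)) + element + "".join(rng.choice(bases, 150))
        utr = "".join(rng.choice(bases, 80)) + element + "".join(rng.choice(bases, 80))
        call = predict_trans(lnc, utr)
        assert call.label == "miRNA_sequestration"
        assert call.align_score >= 22 and call.align_identity >= 0.85

    def test_four_scattered_mismatches_fall_below_score_gate(self):
        element = "ACGTACGTACGTACGTACGTAC"
        mutated = list(element)
        for pos, base in ((3, "A"), (8, "T"), (13, "G"), (18, "C")):
            assert mutated[pos] != base
            mutated[pos] = base
        mutated = "".join(mutated)
        assert local_align(element, mutated).score == 14
        assert predict_trans(element, mutated).label == "none"

    def test_detection_decreases_with_mutation_count(self):
        rng = np.random.default_rng(4)
        bases = list("ACGT")
        rates = []
        for n_mut in (0, 3, 6):
            hits = 0
            for _ in range(40):
                element = "".join(rng.choice(bases, 22))
                mutated = list(element)
                for pos in rng.choice(22, size=n_mut, replace=False):
                    mutated[pos] = rng.choice([b for b in bases if b != mutated[pos]])
                lnc = "".join(rng.choice(bases, 60)) + element + "".join(rng.choice(bases, 60))
                utr = "".join(rng.choice(bases, 40)) + "".join(mutated) + "".join(rng.choice(bases, 40))
                hits += predict_trans(lnc, utr).label == "miRNA_sequestration"
            rates.append(hits / 40)
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]

    def test_random_pairs_rarely_called(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        calls = sum(
            predict_trans(
                "".join(rng.choice(bases, 500)), "".join(rng.choice(bases, 300))
            ).label == "miRNA_sequestration"
            for _ in range(120)
        )
        assert calls / 120 <= 0.01


class TestPredictTargets:
    def test_pairs_without_evidence_dropped_and_counted(self, small_study):
        study = small_study
        planted_cis = next(iter(study.truth.cis_truth))
        planted_trans = next(iter(study.truth.trans_truth))
        plain = next(
            (p.lnc, p.mrna) for p in study.truth.pairs
            if p.cis_class is None and (p.lnc, p.mrna) not in study.truth.trans_truth
        )
        pairs = pd.DataFrame(
            {
                "lnc_probe_id": [planted_cis[0], planted_trans[0], plain[0]],
                "mrna_probe_id": [planted_cis[1], planted_trans[1], plain[1]],
                "r": [0.999, 0.995, -0.993],
                "p": [1e-6, 1e-5, 1e-4],
                "n": [6, 6, 6],
                "direction": ["up-up", "up-down", "down-down"],
            }
        )
        table, summary = predict_targets(pairs, study.annotation, study.sequences)
        assert summary["n_dropped_no_evidence"] == 1
        kept = set(zip(table["lncRNA"], table["mRNA"]))
        assert planted_cis in kept and planted_trans in kept and plain not in kept
        by_pair = table.set_index(["lncRNA", "mRNA"])
        assert by_pair.loc[planted_trans, "transregulation"] == "miRNA sequestration"
        assert by_pair.loc[planted_trans, "cisregulation"] == ""
        assert by_pair.loc[planted_cis, "cisregulation"] != ""

    def test_missing_sequence_skips_trans_only(self, small_study):
        study = small_study
        planted_cis = next(iter(study.truth.cis_truth))
        pairs = pd.DataFrame(
            {
                "lnc_probe_id": [planted_cis[0]], "mrna_probe_id": [planted_cis[1]],
                "r": [0.999], "p": [1e-6], "n": [6], "direction": ["up-up"],
            }
        )
        table, summary = predict_targets(pairs, study.annotation, {})
        assert summary["n_missing_sequence"] == 1
        assert len(table) == 1 and table.iloc[0]["transregulation"] == ""
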