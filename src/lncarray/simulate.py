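"""Synthetic study generator with known ground truth.

The microarray data behind the original radioresistance screen were never
deposited, so every pipeline stage is exercised against a simulated study
that reproduces the design: two conditions (radioresistant case vs parental
control), three post-irradiation time points (0/2/48 h), three replicates
per cell, lncRNA and mRNA probes.

Expression follows a log-normal intensity model: log2 intensity =
per-probe baseline (uniform over ``baseline_log2_mean_range``) + a
differential-expression effect of +/- ``de_effect_log2`` for planted DE
probes in case samples at the probe's time points + a shared latent factor
for planted co-expressed lncRNA-mRNA pairs + Normal(0, ``probe_sd``) noise;
the exported matrix is linear (2^x). Planted co-expressed pairs share, within
each time point, a per-sample latent Normal(0, ``pair_latent_sd``) term added
to both members (sign-flipped for anti-correlated pairs) on top of a strong
condition shift of ``pair_de_effect_log2`` per member, so the pair is both
strongly dysregulated (entering the DE-restricted candidate universe) and
near-perfectly correlated across the six samples of a time point — the only
regime that can survive an |r| > 0.99 filter at n = 6. A subset of the
pairs receives cis geometry (the lncRNA locus is placed to realize a chosen
positional class relative to the partner gene) and another subset receives a
shared random sequence element copied into both the lncRNA and the partner's
3'UTR (the trans/miRNA-sequestration signal). The remaining pairs have
neither, exercising the drop rule of target prediction.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` streams, so identical seeds give byte-identical
outputs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import study_io
from .study_io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    Sample,
    StudyDesign,
    TranscriptAnnotation,
    TranscriptRecord,
)

TIME_POINTS = ("T0", "T2", "T48")
_STREAMS = ("geometry", "expression", "sequences", "assignment", "assays", "genesets")

#: Gene placement geometry (bp): span/exon layout of every synthetic gene.
_GENE_SPACING = 50_000
_GENE_EXONS = ((0, 500), (2_000, 2_600), (4_400, 5_000))  # offsets within the gene
_GENE_LENGTH = 5_000
_LNC_LENGTH = 600


@dataclass
class SimulationConfig:
    n_lnc: int = 300
    n_mrna: int = 700
    replicates: int = 3
    baseline_log2_mean_range: tuple[float, float] = (4.0, 16.0)
    probe_sd: float = 0.25
    de_fraction: float = 0.05          # per direction per time point
    de_effect_log2: float = 2.0
    coexpressed_pair_count: int = 30
    pair_latent_sd: float = 1.5
    pair_de_effect_log2: float = 6.0   # condition shift of pair members (log2)
    cis_pair_count: int = 12           # cycled through cis_geometries
    cis_geometries: tuple[str, ...] = (
        "Sense", "Antisense", "Intronic", "Bidirectional", "Divergent", "Intergenic10k",
    )
    trans_pair_count: int = 10
    shared_element_length: int = 22
    lnc_seq_length: int = 400
    utr3_seq_length: int = 300
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000_000, "chr2": 200_000_000}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required (no silent nondeterminism)")
        if self.probe_sd <= 0 or self.de_effect_log2 <= 0:
            raise ValueError("probe_sd and de_effect_log2 must be positive")
        if min(self.n_lnc, self.n_mrna, self.replicates) <= 0:
            raise ValueError("n_lnc, n_mrna, replicates must be positive")
        if not 0 <= self.de_fraction < 0.5:
            raise ValueError("de_fraction must lie in [0, 0.5) per direction")
        if self.cis_pair_count + self.trans_pair_count > self.coexpressed_pair_count:
            raise ValueError("cis + trans pair counts exceed coexpressed_pair_count")
        if self.coexpressed_pair_count > min(self.n_lnc, self.n_mrna):
            raise ValueError("coexpressed_pair_count exceeds probe pool size")
        needed = (self.n_mrna + 1) * _GENE_SPACING
        if needed > self.chrom_sizes.get("chr1", 0):
            raise ValueError(
                f"chr1 too small for {self.n_mrna} genes at {_GENE_SPACING} bp spacing "
                f"(need {needed} bp)"
            )
        if (self.n_lnc + 1) * _GENE_SPACING > self.chrom_sizes.get("chr2", 0):
            raise ValueError("chr2 too small for the lncRNA pool")


@dataclass
class PlantedPair:
    lnc: str
    mrna: str
    sign: int                 # +1 correlated, -1 anti-correlated
    lnc_direction: str        # DE regulation of the lncRNA member
    mrna_direction: str
    cis_class: str | None = None
    trans_element: str | None = None


@dataclass
class TruthSet:
    de_truth: dict[str, dict[str, str]]          # time_point -> probe -> up/down
    pairs: list[PlantedPair]
    cis_truth: dict[tuple[str, str], str]
    trans_truth: set[tuple[str, str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_truth": self.de_truth,
                "pairs": [dataclasses.asdict(p) for p in self.pairs],
                "cis_truth": {f"{l}|{m}": c for (l, m), c in sorted(self.cis_truth.items())},
                "trans_truth": sorted(f"{l}|{m}" for l, m in self.trans_truth),
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticStudy:
    matrix: ExpressionMatrix          # linear scale, unnormalized
    design: StudyDesign
    annotation: TranscriptAnnotation
    sequences: dict[str, str]         # probe_id -> lncRNA transcript or mRNA 3'UTR seq
    truth: TruthSet
    gene_sets: GeneSetCollection | None = None


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _make_design(replicates: int) -> StudyDesign:
    samples = []
    for tp in TIME_POINTS:
        for condition, prefix in (("case", "RS"), ("control", "P")):
            for rep in range(1, replicates + 1):
                samples.append(Sample(f"{prefix}_{tp}_{rep}", condition, tp, rep))
    return StudyDesign(samples)


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> dict[str, TranscriptRecord]:
    """mRNA genes in tandem along chr1, strands random, 3'UTR in the last exon."""
    records: dict[str, TranscriptRecord] = {}
    strands = rng.choice(["+", "-"], size=config.n_mrna)
    for i in range(config.n_mrna):
        probe = f"mrna{i:05d}"
        start = (i + 1) * _GENE_SPACING
        exons = [(start + s, start + e) for s, e in _GENE_EXONS]
        strand = str(strands[i])
        utr_len = min(config.utr3_seq_length, 300)
        if strand == "+":
            utr3 = (exons[-1][1] - utr_len, exons[-1][1])
        else:
            utr3 = (exons[0][0], exons[0][0] + utr_len)
        records[probe] = TranscriptRecord(
            probe_id=probe, rna_type="mRNA", transcript_id=f"NM_{i:05d}",
            gene_id=f"GENE{i:05d}", chrom="chr1", strand=strand,
            start=start, end=start + _GENE_LENGTH, exons=exons, utr3=utr3,
        )
    return records


def _place_lnc_default(i: int) -> tuple[str, str, int, int]:
    """Default lncRNA placement: isolated on chr2, > 10 kb from any neighbour."""
    start = (i + 1) * _GENE_SPACING
    return "chr2", "+", start, start + _LNC_LENGTH


def _place_lnc_cis(
    gene: TranscriptRecord, cis_class: str, config: SimulationConfig
) -> tuple[str, str, int, int]:
    """Coordinates realizing ``cis_class`` relative to ``gene``."""
    if cis_class == "Sense":
        s, e = gene.exons[1]
        return gene.chrom, gene.strand, s, e
    if cis_class == "Antisense":
        strand = "-" if gene.strand == "+" else "+"
        return gene.chrom, strand, gene.start + 200, gene.start + 200 + _LNC_LENGTH
    if cis_class == "Intronic":
        intron = gene.introns()[0]
        return gene.chrom, gene.strand, intron[0] + 200, intron[0] + 200 + _LNC_LENGTH
    if cis_class in ("Bidirectional", "Divergent"):
        gap = 500 if cis_class == "Bidirectional" else 3_000
        if gene.strand == "+":   # gene 5' at start: lncRNA upstream on '-'
            end = gene.start - gap
            return gene.chrom, "-", end - _LNC_LENGTH, end
        start = gene.end + gap   # gene 5' at end: lncRNA downstream on '+'
        return gene.chrom, "+", start, start + _LNC_LENGTH
    if cis_class == "Intergenic10k":
        gap = 8_000
        end = gene.start - gap
        return gene.chrom, gene.strand, end - _LNC_LENGTH, end
    raise ValueError(f"unknown cis class {cis_class!r}")


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate expression, design, annotation, sequences and ground truth."""
    rng = _streams(config.seed)
    design = _make_design(config.replicates)

    lnc_probes = [f"lnc{i:05d}" for i in range(config.n_lnc)]
    mrna_records = _place_genes(config, rng["geometry"])
    mrna_probes = list(mrna_records)

    # --- planted co-expressed pairs ----------------------------------------
    assign = rng["assignment"]
    pair_lnc = assign.choice(config.n_lnc, size=config.coexpressed_pair_count, replace=False)
    pair_mrna = assign.choice(config.n_mrna, size=config.coexpressed_pair_count, replace=False)
    signs = assign.choice([1, -1], size=config.coexpressed_pair_count)
    lnc_dirs = assign.choice(["up", "down"], size=config.coexpressed_pair_count)

    pairs: list[PlantedPair] = []
    cis_truth: dict[tuple[str, str], str] = {}
    trans_truth: set[tuple[str, str]] = set()
    for idx in range(config.coexpressed_pair_count):
        lnc = lnc_probes[pair_lnc[idx]]
        mrna = mrna_probes[pair_mrna[idx]]
        sign = int(signs[idx])
        lnc_dir = str(lnc_dirs[idx])
        mrna_dir = lnc_dir if sign == 1 else ("down" if lnc_dir == "up" else "up")
        pair = PlantedPair(lnc, mrna, sign, lnc_dir, mrna_dir)
        if idx < config.cis_pair_count:
            pair.cis_class = config.cis_geometries[idx % len(config.cis_geometries)]
            cis_truth[(lnc, mrna)] = pair.cis_class
        elif idx < config.cis_pair_count + config.trans_pair_count:
            trans_truth.add((lnc, mrna))
        pairs.append(pair)

    # --- lncRNA placement ---------------------------------------------------
    lnc_records: dict[str, TranscriptRecord] = {}
    cis_by_lnc = {p.lnc: p for p in pairs if p.cis_class is not None}
    for i, probe in enumerate(lnc_probes):
        if probe in cis_by_lnc:
            pair = cis_by_lnc[probe]
            chrom, strand, start, end = _place_lnc_cis(
                mrna_records[pair.mrna], pair.cis_class, config
            )
            if start < 0 or end > config.chrom_sizes[chrom]:
                raise ValueError(
                    f"cis geometry {pair.cis_class!r} impossible for chrom size at {probe}"
                )
        else:
            chrom, strand, start, end = _place_lnc_default(i)
            if end > config.chrom_sizes[chrom]:
                raise ValueError(f"chrom {chrom} too small for lncRNA {probe}")
        lnc_records[probe] = TranscriptRecord(
            probe_id=probe, rna_type="lncRNA", transcript_id=f"LNCT_{i:05d}",
            gene_id=f"LNCG_{i:05d}", chrom=chrom, strand=strand,
            start=start, end=end, exons=[(start, end)],
        )
    annotation = TranscriptAnnotation({**lnc_records, **mrna_records})

    # --- DE truth ------------------------------------------------------------
    all_probes = lnc_probes + mrna_probes
    pair_members = {p.lnc for p in pairs} | {p.mrna for p in pairs}
    free_probes = np.array([p for p in all_probes if p not in pair_members])
    n_de_per_direction = int(round(config.de_fraction * len(all_probes)))
    de_truth: dict[str, dict[str, str]] = {tp: {} for tp in TIME_POINTS}
    for tp in TIME_POINTS:
        # pair members are consistently dysregulated at every time point
        for pair in pairs:
            de_truth[tp][pair.lnc] = pair.lnc_direction
            de_truth[tp][pair.mrna] = pair.mrna_direction
        if n_de_per_direction and len(free_probes):
            chosen = assign.choice(
                free_probes, size=min(2 * n_de_per_direction, len(free_probes)), replace=False
            )
            for probe in chosen[:n_de_per_direction]:
                de_truth[tp][str(probe)] = "up"
            for probe in chosen[n_de_per_direction:]:
                de_truth[tp][str(probe)] = "down"

    # --- expression ----------------------------------------------------------
    erng = rng["expression"]
    probe_index = {p: i for i, p in enumerate(all_probes)}
    n_probes = len(all_probes)
    sample_ids = [s.sample_id for s in design.samples]
    n_samples = len(sample_ids)
    lo, hi = config.baseline_log2_mean_range
    baseline = erng.uniform(lo, hi, size=n_probes)
    # co-expressed pair members share one central baseline so that their
    # trajectories stay comparable after rank-based normalization
    margin = min(2.0, (hi - lo) / 4)
    for pair in pairs:
        shared = erng.uniform(lo + margin, hi - margin)
        baseline[probe_index[pair.lnc]] = shared
        baseline[probe_index[pair.mrna]] = shared
    log2 = baseline[:, None] + erng.normal(0.0, config.probe_sd, size=(n_probes, n_samples))

    col = {sid: j for j, sid in enumerate(sample_ids)}
    for tp in TIME_POINTS:
        case_cols = [col[s] for s in design.sample_ids("case", tp)]
        tp_cols = [col[s] for s in design.sample_ids(time_point=tp)]
        for probe, direction in de_truth[tp].items():
            effect = (
                config.pair_de_effect_log2 if probe in pair_members else config.de_effect_log2
            )
            delta = effect if direction == "up" else -effect
            log2[probe_index[probe], case_cols] += delta
        for pair in pairs:
            latent = erng.normal(0.0, config.pair_latent_sd, size=len(tp_cols))
            log2[probe_index[pair.lnc], tp_cols] += latent
            log2[probe_index[pair.mrna], tp_cols] += pair.sign * latent

    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2), index=all_probes, columns=sample_ids),
        scale="linear",
    )

    # --- sequences -----------------------------------------------------------
    srng = rng["sequences"]
    bases = np.array(list("ACGT"))

    def _random_seq(length: int) -> str:
        return "".join(srng.choice(bases, size=length))

    sequences = {p: _random_seq(config.lnc_seq_length) for p in lnc_probes}
    sequences.update({p: _random_seq(config.utr3_seq_length) for p in mrna_probes})
    for pair in pairs:
        if (pair.lnc, pair.mrna) not in trans_truth:
            continue
        element = _random_seq(config.shared_element_length)
        pair.trans_element = element
        for probe, seq_len in (
            (pair.lnc, config.lnc_seq_length),
            (pair.mrna, config.utr3_seq_length),
        ):
            pos = int(srng.integers(0, seq_len - config.shared_element_length + 1))
            seq = sequences[probe]
            sequences[probe] = seq[:pos] + element + seq[pos + len(element):]

    truth = TruthSet(de_truth=de_truth, pairs=pairs, cis_truth=cis_truth,
                     trans_truth=trans_truth)
    gene_sets = simulate_gene_sets(annotation, truth, rng["genesets"])
    return SyntheticStudy(matrix, design, annotation, sequences, truth, gene_sets)


def simulate_gene_sets(
    annotation: TranscriptAnnotation,
    truth: TruthSet,
    rng: np.random.Generator,
    n_random_sets: int = 15,
    set_size: int = 25,
) -> GeneSetCollection:
    """Gene sets over the array's mRNA genes: one set enriched in planted DE
    genes per time point plus random background sets."""
    mrna_probes = annotation.probes_of_type("mRNA")
    universe = sorted({annotation[p].gene_id for p in mrna_probes})
    gene_of = {p: annotation[p].gene_id for p in mrna_probes}
    sets = []
    for tp in TIME_POINTS:
        de_genes = sorted({gene_of[p] for p in truth.de_truth[tp] if p in gene_of})
        if not de_genes:
            continue
        core = list(rng.choice(de_genes, size=min(set_size, len(de_genes)), replace=False))
        pad_pool = [g for g in universe if g not in core]
        pad = list(rng.choice(pad_pool, size=max(0, set_size - len(core)), replace=False))
        sets.append(GeneSet(f"PLANTED_{tp}", f"enriched in {tp} DE genes",
                            frozenset(core + pad)))
    for i in range(n_random_sets):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets.append(GeneSet(f"RANDOM_{i:02d}", "background set", frozenset(members)))
    return GeneSetCollection(sets)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "sample_sheet": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "lnc_fasta": out / "lncrna.fasta",
        "utr3_fasta": out / "utr3.fasta",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    study_io.write_expression_matrix(study.matrix, paths["expression"])
    study_io.write_sample_sheet(study.design, paths["sample_sheet"])
    study_io.write_annotation(study.annotation, paths["annotation"])
    lnc_ids = set(study.annotation.probes_of_type("lncRNA"))
    study_io.write_fasta(
        {k: v for k, v in study.sequences.items() if k in lnc_ids}, paths["lnc_fasta"]
    )
    study_io.write_fasta(
        {k: v for k, v in study.sequences.items() if k not in lnc_ids}, paths["utr3_fasta"]
    )
    if study.gene_sets is not None:
        study_io.write_gene_sets(study.gene_sets, paths["gene_sets"])
    paths["truth"].write_text(study.truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# assay simulation
# ---------------------------------------------------------------------------

@dataclass
class AssayConfig:
    seed: int | None = None
    noise: float = 1.0                 # 0 disables sampling (exact expectations)
    replicates: int = 3
    doses: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    seeded: tuple[int, ...] = (300, 600, 900, 1200)
    #: LQ parameters per cell line; the case line survives better (radioresistant)
    lq_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"RS": (0.20, 0.020), "parental": (0.35, 0.035)}
    )
    plating_efficiency: dict[str, float] = field(
        default_factory=lambda: {"RS": 0.5, "parental": 0.5}
    )
    apoptosis_times: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    #: total apoptotic fraction means per line per time (early:late split 2:1)
    apoptosis_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "RS": (0.05, 0.10, 0.15, 0.18),
            "parental": (0.05, 0.22, 0.33, 0.40),
        }
    )
    qpcr_targets: dict[str, float] = field(
        default_factory=lambda: {"lncA": 3.0, "lncB": -1.0, "mrnaC": 5.0}
    )  # true dCT per target
    qpcr_ct_reference: float = 20.0
    qpcr_ct_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        for line, (alpha, beta) in self.lq_params.items():
            for d in self.doses:
                sf = float(np.exp(-(alpha * d + beta * d * d)))
                if not 0 < sf <= 1:
                    raise ValueError(f"true SF outside (0, 1] for {line} at {d} Gy")


def true_survival_fraction(alpha: float, beta: float, dose: float) -> float:
    return float(np.exp(-(alpha * dose + beta * dose * dose)))


def simulate_assays(config: AssayConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Clonogenic, apoptosis and qPCR records with their ground truth.

    Colony counts are Binomial(seeded, SF x PE); apoptosis quadrant fractions
    are Dirichlet around the true quadrant means; CT triplicates are Normal
    around the true dCT. With ``noise = 0`` every record equals its
    expectation (rounded for counts) and the downstream arithmetic recovers
    the truth exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    clono_rows = []
    for line in sorted(config.lq_params):
        alpha, beta = config.lq_params[line]
        pe = config.plating_efficiency[line]
        for dose, seeded in zip(config.doses, config.seeded):
            sf = true_survival_fraction(alpha, beta, dose)
            p = sf * pe
            for rep in range(1, config.replicates + 1):
                if config.noise == 0:
                    colonies = int(round(p * seeded))
                else:
                    colonies = int(rng.binomial(seeded, p))
                clono_rows.append((line, dose, seeded, colonies, rep))
    clonogenic = pd.DataFrame(clono_rows, columns=[
        "cell_line", "dose", "cells_seeded", "colonies", "replicate"])

    apo_rows = []
    for line in sorted(config.apoptosis_means):
        for time_h, total in zip(config.apoptosis_times, config.apoptosis_means[line]):
            means = np.array([total * 2 / 3, total / 3, 1 - total - 0.02, 0.02])
            for rep in range(1, config.replicates + 1):
                if config.noise == 0:
                    q = means
                else:
                    q = rng.dirichlet(means * 500.0 / config.noise)
                apo_rows.append((line, time_h, rep, q[0], q[1], q[2], q[3]))
    apoptosis = pd.DataFrame(apo_rows, columns=[
        "cell_line", "time_h", "replicate",
        "annexin_pos_pi_neg", "annexin_pos_pi_pos", "annexin_neg_pi_neg", "annexin_neg_pi_pos",
    ])

    qpcr_rows = []
    for target in sorted(config.qpcr_targets):
        dct = config.qpcr_targets[target]
        for rep in range(1, config.replicates + 1):
            sd = config.qpcr_ct_sd * config.noise
            ct_ref = config.qpcr_ct_reference + (rng.normal(0, sd) if sd > 0 else 0.0)
            ct_tgt = config.qpcr_ct_reference + dct + (rng.normal(0, sd) if sd > 0 else 0.0)
            qpcr_rows.append((target, rep, ct_tgt, ct_ref))
    qpcr = pd.DataFrame(qpcr_rows, columns=["target_id", "replicate", "ct_target", "ct_reference"])

    truth = {
        "lq_params": dict(config.lq_params),
        "plating_efficiency": dict(config.plating_efficiency),
        "survival_fractions": {
            line: {d: true_survival_fraction(a, b, d) for d in config.doses}
            for line, (a, b) in config.lq_params.items()
        },
        "apoptosis_totals": {
            line: dict(zip(config.apoptosis_times, totals))
            for line, totals in config.apoptosis_means.items()
        },
        "qpcr_relative_expression": {
            t: 2.0 ** (-dct) for t, dct in config.qpcr_targets.items()
        },
    }
    return clonogenic, apoptosis, qpcr, truth
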