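"""cis/trans target prediction for correlated lncRNA-mRNA pairs.

cis prediction asks whether the lncRNA locus lies within a 10 kb genomic
window of the partner gene and assigns a single positional class by
precedence: same-strand exonic overlap (Sense) > opposite-strand overlap
(Antisense) > containment in an intron without exonic overlap (Intronic) >
head-to-head promoters within 1 kb (Bidirectional) > head-to-head within
5 kb (Divergent) > any configuration with an interval gap <= 10 kb
(Intergenic10k). Overlapping loci have distance 0; otherwise the distance
is the gap between the transcript spans.

trans prediction models miRNA sequestration (the ceRNA hypothesis): a lncRNA
sharing a miRNA-response-element-like stretch with an mRNA 3'UTR competes
for the same miRNAs. It is operationalized as Smith-Waterman local alignment
of the lncRNA sequence to the 3'UTR with +1/-1 match/mismatch and a linear
gap penalty of -2; a hit needs score >= 16 and >= 85% identity, sized to a
~22 nt element. The thresholds and scoring are package conventions (no
standard is fixed for this step) and are all configurable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .study_io import TranscriptAnnotation, TranscriptRecord

log = logging.getLogger(__name__)

CIS_CLASSES = ("Sense", "Antisense", "Intronic", "Bidirectional", "Divergent", "Intergenic10k")

#: Output spellings used in the pair tables.
CIS_OUTPUT_LABELS = {**{c: c for c in CIS_CLASSES}, "Intergenic10k": "Intergenic (10 k)"}
TRANS_OUTPUT_LABEL = "miRNA sequestration"


@dataclass
class TargetPredConfig:
    cis_window: int = 10_000
    bidirectional_tss_gap: int = 1_000
    divergent_tss_gap: int = 5_000
    align_match: int = 1
    align_mismatch: int = -1
    align_gap: int = -2
    min_align_score: int = 16
    min_identity: float = 0.85

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not self.bidirectional_tss_gap <= self.divergent_tss_gap <= self.cis_window:
            raise ValueError("need bidirectional_tss_gap <= divergent_tss_gap <= cis_window")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class CisCall:
    label: str              # one of CIS_CLASSES or "none"
    distance: int | None    # 0 for overlaps; None when label == "none" off-window/chromosome


@dataclass
class TransCall:
    label: str              # "miRNA_sequestration" | "none"
    align_score: int        # best qualifying core window (falls back to the optimum)
    align_identity: float
    lnc_span: tuple[int, int] | None
    utr_span: tuple[int, int] | None


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases strictly between two half-open intervals (0 when they touch/overlap)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _five_prime(rec: TranscriptRecord) -> int:
    return rec.start if rec.strand == "+" else rec.end


def classify_cis(
    lnc: TranscriptRecord, gene: TranscriptRecord, config: TargetPredConfig | None = None
) -> CisCall:
    """Assign the positional class of a lncRNA relative to a candidate gene."""
    config = config or TargetPredConfig()
    for rec in (lnc, gene):
        if rec.strand not in ("+", "-"):
            raise ValueError(f"malformed strand for {rec.probe_id}")
    if lnc.chrom != gene.chrom:
        return CisCall("none", None)

    span_overlap = _intervals_overlap(lnc.span, gene.span)
    same_strand = lnc.strand == gene.strand

    # (1) exonic overlap on the same strand
    if same_strand and any(
        _intervals_overlap(le, ge) for le in lnc.exons for ge in gene.exons
    ):
        return CisCall("Sense", 0)
    # (2) any span overlap on the opposite strand
    if not same_strand and span_overlap:
        return CisCall("Antisense", 0)
    # (3) lncRNA span contained in one gene intron, no exonic overlap
    # (rules 1-2 already returned on any exonic or opposite-strand overlap)
    if any(intron[0] <= lnc.start and lnc.end <= intron[1] for intron in gene.introns()):
        return CisCall("Intronic", 0)

    if span_overlap:
        # same-strand span overlap avoiding every exon and not intron-contained
        return CisCall("Intergenic10k", 0)

    gap = _gap(lnc.span, gene.span)
    # (4)/(5) head-to-head promoters on opposite strands
    if not same_strand:
        left, right = (lnc, gene) if lnc.start <= gene.start else (gene, lnc)
        head_to_head = left.strand == "-" and right.strand == "+"
        if head_to_head and _five_prime(left) <= _five_prime(right):
            if gap <= config.bidirectional_tss_gap:
                return CisCall("Bidirectional", gap)
            if gap <= config.divergent_tss_gap:
                return CisCall("Divergent", gap)
    # (6) anything else within the window
    if gap <= config.cis_window:
        return CisCall("Intergenic10k", gap)
    return CisCall("none", None)


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    score: int
    identity: float                    # matches / aligned columns (gaps count)
    a_span: tuple[int, int] | None     # half-open on sequence a
    b_span: tuple[int, int] | None
    aligned_a: str = ""
    aligned_b: str = ""


def local_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> AlignmentResult:
    """Smith-Waterman optimum with linear gap penalty.

    'N' scores as a mismatch against anything. Traceback is deterministic:
    the best cell is the highest-scoring one with the lowest row then lowest
    column, and at each step diagonal moves are preferred over up (gap in b)
    over left (gap in a). Empty input yields score 0.
    """
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return AlignmentResult(0, 0.0, None, None)
    g = -gap  # positive penalty
    if g <= 0:
        raise ValueError("gap penalty must be negative")

    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")
    h = np.zeros((n + 1, m + 1), dtype=np.int64)
    idx_pen = np.arange(m + 1, dtype=np.int64) * g
    for i in range(1, n + 1):
        eq = (a_arr[i - 1] == b_arr) & (a_arr[i - 1] != n_code) & (b_arr != n_code)
        sub = np.where(eq, match, mismatch).astype(np.int64)
        cand = np.zeros(m + 1, dtype=np.int64)
        cand[1:] = h[i - 1, :-1] + sub            # diagonal
        np.maximum(cand, h[i - 1] - g, out=cand)  # up (gap in b)
        np.maximum(cand, 0, out=cand)
        # left gaps: h[i,j] = max(cand[j], h[i,j-1] - g) via prefix scan
        h[i] = np.maximum.accumulate(cand + idx_pen) - idx_pen
        h[i, 0] = 0

    best = int(h.max())
    if best == 0:
        return AlignmentResult(0, 0.0, None, None)
    flat = int(np.argmax(h))  # first max in row-major order: lowest row, then column
    i, j = divmod(flat, m + 1)

    aligned_a: list[str] = []
    aligned_b: list[str] = []
    end_i, end_j = i, j
    while i > 0 and j > 0 and h[i, j] > 0:
        is_match = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
        sub = match if is_match else mismatch
        if h[i, j] == h[i - 1, j - 1] + sub:
            aligned_a.append(a[i - 1])
            aligned_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif h[i, j] == h[i - 1, j] - g:
            aligned_a.append(a[i - 1])
            aligned_b.append("-")
            i -= 1
        else:
            aligned_a.append("-")
            aligned_b.append(b[j - 1])
            j -= 1
    aligned_a.reverse()
    aligned_b.reverse()
    columns = len(aligned_a)
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x not in ("-", "N")
    )
    return AlignmentResult(
        score=best,
        identity=matches / columns if columns else 0.0,
        a_span=(i, end_i),
        b_span=(j, end_j),
        aligned_a="".join(aligned_a),
        aligned_b="".join(aligned_b),
    )


def _best_core_window(
    aligned_a: str, aligned_b: str, match: int, mismatch: int, gap: int, min_score: int
) -> tuple[int, float] | None:
    """Highest-identity contiguous window of an alignment with score >= min_score.

    Returns (score, identity) of the best window, or None if no window reaches
    the score threshold. Gap columns count against identity and score.
    """
    col_scores = []
    col_match = []
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            col_scores.append(gap)
            col_match.append(0)
        elif x == y and x != "N":
            col_scores.append(match)
            col_match.append(1)
        else:
            col_scores.append(mismatch)
            col_match.append(0)
    n = len(col_scores)
    best: tuple[float, int] | None = None  # (identity, score)
    for i in range(n):
        score = 0
        matches = 0
        for j in range(i, n):
            score += col_scores[j]
            matches += col_match[j]
            if score >= min_score:
                identity = matches / (j - i + 1)
                if best is None or (identity, score) > best:
                    best = (identity, score)
    if best is None:
        return None
    return best[1], best[0]


def predict_trans(
    lnc_seq: str, utr3_seq: str, config: TargetPredConfig | None = None
) -> TransCall:
    """Call miRNA sequestration when the lncRNA shares a 3'UTR-like element.

    The score/identity gates are evaluated over contiguous segments of the
    optimal local alignment, not only its full extent: a high-identity core
    (a shared ~22 nt element) flanked by low-identity but score-positive
    extension still qualifies, because the optimal alignment greedily absorbs
    any extension that raises the score even marginally.
    """
    config = config or TargetPredConfig()
    aln = local_align(
        lnc_seq, utr3_seq, config.align_match, config.align_mismatch, config.align_gap
    )
    hit = False
    core_score, core_identity = aln.score, aln.identity
    if aln.score >= config.min_align_score:
        window = _best_core_window(
            aln.aligned_a, aln.aligned_b,
            config.align_match, config.align_mismatch, config.align_gap,
            config.min_align_score,
        )
        if window is not None:
            core_score, core_identity = window
            hit = core_identity >= config.min_identity
    return TransCall(
        label="miRNA_sequestration" if hit else "none",
        align_score=core_score,
        align_identity=core_identity,
        lnc_span=aln.a_span,
        utr_span=aln.b_span,
    )


# ---------------------------------------------------------------------------
# combined table
# ---------------------------------------------------------------------------

TARGET_TABLE_COLUMNS = [
    "lncRNA", "mRNA", "Correlation", "P-value", "Direction",
    "cisregulation", "transregulation",
]


def predict_targets(
    pairs: pd.DataFrame,
    annotation: TranscriptAnnotation,
    sequences: Mapping[str, str],
    config: TargetPredConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Combine cis and trans evidence for retained correlation pairs.

    ``pairs`` is the output of :func:`lncarray.coexpression.pair_correlations`;
    ``sequences`` maps probe ids to lncRNA transcript / mRNA 3'UTR sequences.
    A pair appears in the output only with a cis class or a trans label;
    pairs with neither are dropped and counted in the summary. Returns the
    table (target-table column layout) and a summary dict of per-class
    counts.
    """
    config = config or TargetPredConfig()
    rows = []
    summary = {
        "n_pairs_in": len(pairs),
        "n_dropped_no_evidence": 0,
        "n_missing_annotation": 0,
        "n_missing_sequence": 0,
        "cis_counts": {},
        "n_trans": 0,
    }
    for row in pairs.itertuples(index=False):
        lnc_rec = annotation.get(row.lnc_probe_id)
        gene_rec = annotation.get(row.mrna_probe_id)
        if lnc_rec is None or gene_rec is None:
            summary["n_missing_annotation"] += 1
            log.info("pair (%s, %s): annotation missing; cis skipped",
                     row.lnc_probe_id, row.mrna_probe_id)
            cis = CisCall("none", None)
        else:
            cis = classify_cis(lnc_rec, gene_rec, config)

        lnc_seq = sequences.get(row.lnc_probe_id)
        utr_seq = sequences.get(row.mrna_probe_id)
        if lnc_seq is None or utr_seq is None:
            summary["n_missing_sequence"] += 1
            log.info("pair (%s, %s): sequence missing; trans skipped",
                     row.lnc_probe_id, row.mrna_probe_id)
            trans = TransCall("none", 0, 0.0, None, None)
        else:
            trans = predict_trans(lnc_seq, utr_seq, config)

        if cis.label == "none" and trans.label == "none":
            summary["n_dropped_no_evidence"] += 1
            continue
        if cis.label != "none":
            summary["cis_counts"][cis.label] = summary["cis_counts"].get(cis.label, 0) + 1
        if trans.label != "none":
            summary["n_trans"] += 1
        rows.append(
            (
                row.lnc_probe_id,
                row.mrna_probe_id,
                row.r,
                row.p,
                row.direction,
                CIS_OUTPUT_LABELS.get(cis.label, "") if cis.label != "none" else "",
                TRANS_OUTPUT_LABEL if trans.label != "none" else "",
            )
        )
    return pd.DataFrame(rows, columns=TARGET_TABLE_COLUMNS), summary
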