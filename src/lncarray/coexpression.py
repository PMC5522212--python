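"""Pearson correlation of dysregulated lncRNA-mRNA pairs.

Candidate pairs are the cross product of significantly dysregulated lncRNA
probes and mRNA probes at one time point. The correlation is computed over
the n = 6 samples of that time point (3 case + 3 control replicates, log2
normalized values) and a pair is retained when |r| > 0.99 and the two-sided
p-value of r (t = r*sqrt((n-2)/(1-r^2)) on n-2 df) is below 0.05 — an
intentionally extreme filter meant to keep only near-deterministic
co-expression. n = 6 is an inferred constant (configurable): with df = 4 the
t-distribution reproduces every printed (r, p) pair in the study's target
tables.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study_io import ExpressionMatrix, StudyDesign

log = logging.getLogger(__name__)


@dataclass
class CorrConfig:
    r_threshold: float = 0.99
    p_threshold: float = 0.05
    require_de: bool = True   # restrict candidates to significant probes
    use_log2: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")


class ZeroVarianceError(ValueError):
    """A correlation operand has no variance."""


def pearson_r(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("zero variance operand")
    # rounding can push a collinear pair an ulp beyond +/-1
    return float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided significance of a Pearson coefficient on n-2 df.

    |r| = 1 returns 0 by convention (the t statistic diverges).
    """
    if n < 3:
        raise ValueError("correlation_p needs n >= 3")
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError("r must be in [-1, 1]")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def pair_correlations(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    time_point: str,
    de_lnc: pd.DataFrame,
    de_mrna: pd.DataFrame,
    config: CorrConfig | None = None,
) -> pd.DataFrame:
    """Correlate candidate lncRNA x mRNA probe pairs at one time point.

    Returns retained pairs as a DataFrame with columns lnc_probe_id,
    mrna_probe_id, r, p, n, direction ("up-down" style, lncRNA first, from
    each member's DE regulation call). Zero-variance probes are skipped with
    a log entry rather than propagating NaN.
    """
    config = config or CorrConfig()
    if not matrix.normalized:
        raise ValueError("pair_correlations expects a normalized matrix")
    sample_ids = design.cell("case", time_point) + design.cell("control", time_point)
    n = len(sample_ids)
    if n < 3:
        raise ValueError("need >= 3 samples at the time point")

    def _candidates(de_table: pd.DataFrame) -> pd.DataFrame:
        return de_table[de_table["significant"]] if config.require_de else de_table

    lnc = _candidates(de_lnc)
    mrna = _candidates(de_mrna)
    columns = ["lnc_probe_id", "mrna_probe_id", "r", "p", "n", "direction"]
    if lnc.empty or mrna.empty:
        log.info("empty DE candidate set at %s; no pairs computed", time_point)
        return pd.DataFrame(columns=columns)

    sub = matrix.subset_samples(sample_ids).values
    vals = sub.to_numpy(dtype=float)
    if config.use_log2 and matrix.scale == "linear":
        vals = np.log2(np.maximum(vals, 1.0))
    elif not config.use_log2 and matrix.scale == "log2":
        vals = np.exp2(vals)
    index = {p: i for i, p in enumerate(sub.index)}

    def _rows(de_part: pd.DataFrame) -> tuple[np.ndarray, list[str], dict[str, str]]:
        probes, keep = [], []
        for p in de_part["probe_id"]:
            if p not in index:
                log.info("probe %s absent from matrix; skipped", p)
                continue
            probes.append(p)
            keep.append(index[p])
        block = vals[keep, :]
        sd = block.std(axis=1)
        nonzero = sd > 0
        for p, ok in zip(probes, nonzero):
            if not ok:
                log.info("probe %s has zero variance at %s; skipped", p, time_point)
        regs = dict(zip(de_part["probe_id"], de_part["regulation"]))
        return block[nonzero], [p for p, ok in zip(probes, nonzero) if ok], regs

    lnc_block, lnc_probes, lnc_reg = _rows(lnc)
    mrna_block, mrna_probes, mrna_reg = _rows(mrna)
    if not lnc_probes or not mrna_probes:
        return pd.DataFrame(columns=columns)

    def _standardize(block: np.ndarray) -> np.ndarray:
        centered = block - block.mean(axis=1, keepdims=True)
        return centered / np.sqrt((centered**2).sum(axis=1, keepdims=True))

    r_matrix = np.clip(_standardize(lnc_block) @ _standardize(mrna_block).T, -1.0, 1.0)

    rows = []
    for (i, lp), (j, mp) in itertools.product(enumerate(lnc_probes), enumerate(mrna_probes)):
        r = float(r_matrix[i, j])
        if abs(r) <= config.r_threshold:
            continue
        p = correlation_p(r, n)
        if p >= config.p_threshold:
            continue
        rows.append((lp, mp, r, p, n, f"{lnc_reg[lp]}-{mrna_reg[mp]}"))
    log.info(
        "%s: %d / %d candidate pairs retained by |r| > %g & p < %g",
        time_point, len(rows), len(lnc_probes) * len(mrna_probes),
        config.r_threshold, config.p_threshold,
    )
    return pd.DataFrame(rows, columns=columns)
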