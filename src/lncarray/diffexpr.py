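"""Per-time-point case-vs-control differential expression.

The screen follows classic two-group microarray practice: the fold change is
the ratio of mean linear normalized intensity of the case group
(radioresistant subclone) to the control group (parental line), folded to an
absolute value >= 1 with an up/down direction, and the p-value comes from the
equal-variance two-sample Student's t-test on log2 values. A probe is called
significant when FC(abs) >= 2 and p < 0.05 (both thresholds configurable).
No multiple-testing correction is applied by default, reproducing the raw
p < 0.05 screen; Benjamini-Hochberg can be switched on.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DEFAULT_LOG2_FLOOR
from .study_io import ExpressionMatrix, StudyDesign, TranscriptAnnotation

#: Policy p-value for a zero-pooled-variance comparison with unequal means.
MIN_P = float(np.nextafter(0.0, 1.0))


@dataclass
class DEConfig:
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    top_n: int = 10
    test_scale: str = "log2"   # scale the t-test runs on: "log2" or "linear"
    bh_adjust: bool = False    # off by default: the screen filters on raw p
    log2_floor: float = DEFAULT_LOG2_FLOOR

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.test_scale not in ("log2", "linear"):
            raise ValueError("test_scale must be 'log2' or 'linear'")


class FoldChange(NamedTuple):
    fc_abs: float
    regulation: str  # "up" | "down"
    log2fc_signed: float


def fold_change(
    case_values: np.ndarray | list[float],
    control_values: np.ndarray | list[float],
    floor: float = DEFAULT_LOG2_FLOOR,
) -> FoldChange:
    """Fold change of mean case intensity over mean control intensity.

    Means are floored at ``floor`` before the ratio, so a probe at the floor
    in both groups gets ratio 1 rather than 0/0. ``regulation`` is "up" iff
    the ratio exceeds 1; ``fc_abs`` = max(ratio, 1/ratio).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 1 or control.size < 1:
        raise ValueError("each group needs at least one value")
    if (case < 0).any() or (control < 0).any():
        raise ValueError("negative intensity")
    mean_case = max(case.mean(), floor)
    mean_control = max(control.mean(), floor)
    ratio = mean_case / mean_control
    return FoldChange(
        fc_abs=max(ratio, 1.0 / ratio),
        regulation="up" if ratio > 1 else "down",
        log2fc_signed=float(np.log2(ratio)),
    )


def student_t_test(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> float:
    """Two-sided p from the pooled-variance two-sample t-test (df = nx+ny-2).

    Degenerate policy: zero pooled variance with equal means gives p = 1;
    zero pooled variance with unequal means gives the smallest positive
    float (``MIN_P``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("Student's t-test needs >= 2 values per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        return 1.0 if x.mean() == y.mean() else MIN_P
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return float(2.0 * stats.t.sf(abs(t), nx + ny - 2))


def differential_expression(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    time_point: str,
    config: DEConfig | None = None,
    annotation: TranscriptAnnotation | None = None,
) -> pd.DataFrame:
    """One DE record per probe for ``time_point``.

    Returns a DataFrame with columns probe_id, rna_type, mean_case,
    mean_control, fc_abs, regulation, log2fc_signed, p_value, significant
    (plus p_adjusted when BH is enabled). FC uses linear normalized means,
    the t-test runs on log2 values (configurable).
    """
    config = config or DEConfig()
    if not matrix.normalized:
        raise ValueError("differential expression expects a normalized matrix")
    design.require_replicates(time_point)
    case_ids = design.cell("case", time_point)
    control_ids = design.cell("control", time_point)

    vals = matrix.values
    if matrix.scale == "linear":
        linear = vals.to_numpy(dtype=float)
        log2v = np.log2(np.maximum(linear, config.log2_floor))
    else:
        log2v = vals.to_numpy(dtype=float)
        linear = np.exp2(log2v)
    cols = list(vals.columns)
    case_idx = [cols.index(s) for s in case_ids]
    control_idx = [cols.index(s) for s in control_ids]

    mean_case = np.maximum(linear[:, case_idx].mean(axis=1), config.log2_floor)
    mean_control = np.maximum(linear[:, control_idx].mean(axis=1), config.log2_floor)
    ratio = mean_case / mean_control
    fc_abs = np.maximum(ratio, 1.0 / ratio)
    log2fc = np.log2(ratio)
    regulation = np.where(ratio > 1, "up", "down")

    test_vals = log2v if config.test_scale == "log2" else linear
    p_values = np.array(
        [
            student_t_test(test_vals[i, case_idx], test_vals[i, control_idx])
            for i in range(test_vals.shape[0])
        ]
    )

    table = pd.DataFrame(
        {
            "probe_id": vals.index,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fc_abs": fc_abs,
            "regulation": regulation,
            "log2fc_signed": log2fc,
            "p_value": p_values,
        }
    )
    if annotation is not None:
        table["rna_type"] = [
            annotation[p].rna_type if p in annotation else "unknown" for p in table["probe_id"]
        ]
    p_for_call = p_values
    if config.bh_adjust:
        from .enrichment import bh_adjust

        table["p_adjusted"] = bh_adjust(list(p_values))
        p_for_call = table["p_adjusted"].to_numpy()
    table["significant"] = (fc_abs >= config.fc_threshold) & (p_for_call < config.p_threshold)
    return table


def top_n_table(
    de_table: pd.DataFrame,
    annotation: TranscriptAnnotation | None = None,
    n: int = 10,
    time_point: str = "",
) -> pd.DataFrame:
    """Top-``n`` up- and downregulated significant probes, ranked by FC(abs).

    Ties break by smaller p then lexicographic probe_id, so the table is
    deterministic. Fewer than ``n`` significant probes per direction simply
    yields fewer rows.
    """
    sig = de_table[de_table["significant"]].copy()
    sig = sig.sort_values(
        ["fc_abs", "p_value", "probe_id"], ascending=[False, True, True], kind="stable"
    )
    parts = [sig[sig["regulation"] == direction].head(n) for direction in ("up", "down")]
    top = pd.concat(parts, ignore_index=True) if parts else sig.head(0)

    def _ann(probe: str, field: str) -> str:
        if annotation is not None and probe in annotation:
            value = getattr(annotation[probe], field)
            return "" if value is None else str(value)
        return ""

    return pd.DataFrame(
        {
            "probe_id": top["probe_id"],
            "fc_abs": top["fc_abs"],
            "regulation": top["regulation"],
            "transcript_id": [_ann(p, "transcript_id") for p in top["probe_id"]],
            "chrom": [_ann(p, "chrom") for p in top["probe_id"]],
            "strand": [_ann(p, "strand") for p in top["probe_id"]],
            "gene_id": [_ann(p, "gene_id") for p in top["probe_id"]],
            "class": [_ann(p, "class_label") for p in top["probe_id"]],
            "time_point": time_point,
        }
    ).reset_index(drop=True)


def volcano_table(de_table: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: signed log2 FC vs -log10 p, classed up/down/ns."""
    p = de_table["p_value"].to_numpy(dtype=float)
    p = np.maximum(p, MIN_P)  # p = 0 maps to the policy minimum before -log10
    cls = np.where(de_table["significant"], de_table["regulation"], "ns")
    return pd.DataFrame(
        {
            "probe_id": de_table["probe_id"],
            "log2fc_signed": de_table["log2fc_signed"],
            "neg_log10_p": -np.log10(p),
            "class": cls,
        }
    )


def scatter_table(de_table: pd.DataFrame, floor: float = DEFAULT_LOG2_FLOOR) -> pd.DataFrame:
    """Scatter-plot coordinates: mean log2 control (x) vs mean log2 case (y)."""
    cls = np.where(de_table["significant"], de_table["regulation"], "ns")
    return pd.DataFrame(
        {
            "probe_id": de_table["probe_id"],
            "mean_log2_control": np.log2(np.maximum(de_table["mean_control"], floor)),
            "mean_log2_case": np.log2(np.maximum(de_table["mean_case"], floor)),
            "class": cls,
        }
    )
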