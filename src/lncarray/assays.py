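"""Wet-lab assay arithmetic for the radioresistance phenotype.

Three deterministic calculations back the cell-biology readouts:

* clonogenic survival — plating efficiency PE = colonies/seeded in the
  unirradiated control, survival fraction SF = (colonies/seeded)/PE at each
  dose (default seeding 300/600/900/1200 cells at 0/2/4/6 Gy; colonies with
  more than 50 cells count), with an optional linear-quadratic fit
  ln SF = -(alpha*D + beta*D^2), alpha, beta >= 0;
* apoptosis — total apoptotic fraction = early (Annexin V+/PI-) + late
  (Annexin V+/PI+) flow-cytometry quadrants;
* qRT-PCR — relative expression 2^-dCT with dCT = mean CT(target) -
  mean CT(reference), reference gene beta-actin.

Group comparisons (case vs control at a dose or time) reuse
:func:`lncarray.diffexpr.student_t_test`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

log = logging.getLogger(__name__)

DEFAULT_SEEDING = {0.0: 300, 2.0: 600, 4.0: 900, 6.0: 1200}
APOPTOSIS_SUM_TOL = 1e-6

CLONOGENIC_COLUMNS = ["cell_line", "dose", "cells_seeded", "colonies", "replicate"]
APOPTOSIS_COLUMNS = [
    "cell_line", "time_h", "replicate",
    "annexin_pos_pi_neg", "annexin_pos_pi_pos", "annexin_neg_pi_neg", "annexin_neg_pi_pos",
]
QPCR_COLUMNS = ["target_id", "replicate", "ct_target", "ct_reference"]


@dataclass
class ApoptosisRecord:
    annexin_pos_pi_neg: float   # early apoptosis
    annexin_pos_pi_pos: float   # late apoptosis
    annexin_neg_pi_neg: float   # viable
    annexin_neg_pi_pos: float   # necrotic/debris
    time_h: float = 0.0

    def __post_init__(self) -> None:
        fractions = (
            self.annexin_pos_pi_neg, self.annexin_pos_pi_pos,
            self.annexin_neg_pi_neg, self.annexin_neg_pi_pos,
        )
        if any(f < 0 or f > 1 for f in fractions):
            raise ValueError("quadrant fractions must lie in [0, 1]")
        if sum(fractions) > 1 + APOPTOSIS_SUM_TOL:
            raise ValueError("quadrant fractions sum beyond 1")


def plating_efficiency(colonies_0gy: float, seeded_0gy: float) -> float:
    """PE = colonies observed / cells plated in the unirradiated control."""
    if seeded_0gy <= 0:
        raise ValueError("cells seeded must be positive")
    if colonies_0gy < 0:
        raise ValueError("colony count must be >= 0")
    pe = colonies_0gy / seeded_0gy
    if pe > 1:
        log.warning("plating efficiency %.3f exceeds 1", pe)
    return pe


def survival_fraction(colonies: float, seeded: float, pe: float) -> float:
    """SF = (colonies / cells seeded) / plating efficiency of the control."""
    if pe <= 0:
        raise ValueError("plating efficiency must be positive for SF")
    if seeded <= 0:
        raise ValueError("cells seeded must be positive")
    return (colonies / seeded) / pe


def apoptosis_total(record: ApoptosisRecord) -> float:
    """Total apoptotic fraction = early + late quadrants."""
    return record.annexin_pos_pi_neg + record.annexin_pos_pi_pos


def relative_expression_dct(
    ct_target: list[float] | np.ndarray, ct_reference: list[float] | np.ndarray
) -> float:
    """2^-dCT with dCT = mean CT(target) - mean CT(reference)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if ct_target.size == 0 or ct_reference.size == 0:
        raise ValueError("need >= 1 CT replicate for target and reference")
    for name, ct in (("target", ct_target), ("reference", ct_reference)):
        if ((ct <= 0) | (ct >= 45)).any():
            log.warning("%s CT value(s) outside the plausible (0, 45) range", name)
    dct = ct_target.mean() - ct_reference.mean()
    return float(2.0 ** (-dct))


def fit_linear_quadratic(doses: np.ndarray, sf: np.ndarray) -> tuple[float, float]:
    """Constrained least squares for ln SF = -(alpha*D + beta*D^2), alpha, beta >= 0.

    Rows with SF <= 0 are excluded from the log-scale fit with a warning.
    """
    doses = np.asarray(doses, dtype=float)
    sf = np.asarray(sf, dtype=float)
    keep = sf > 0
    if not keep.all():
        log.warning("excluding %d record(s) with SF <= 0 from the LQ fit", int((~keep).sum()))
    doses, sf = doses[keep], sf[keep]
    if len(np.unique(doses[doses > 0])) < 2:
        raise ValueError("LQ fit needs >= 2 distinct positive doses")
    design = np.column_stack([doses, doses**2])
    target = -np.log(sf)
    coefs, _residual = nnls(design, target)
    return float(coefs[0]), float(coefs[1])


def survival_curve(
    records: pd.DataFrame, fit_lq: bool = False
) -> dict[str, dict]:
    """Per-cell-line dose-response summary from raw clonogenic records.

    ``records`` uses the documented clonogenic CSV schema
    (``cell_line, dose, cells_seeded, colonies, replicate``). For each cell
    line, PE is the mean colonies/seeded over the 0 Gy replicates, each
    record's SF is (colonies/seeded)/PE, and the summary lists per-dose mean
    SF, SD and n. With ``fit_lq`` the linear-quadratic parameters are added.
    """
    missing = set(CLONOGENIC_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"clonogenic records missing column(s): {sorted(missing)}")
    out: dict[str, dict] = {}
    for cell_line, group in records.groupby("cell_line", sort=True):
        control = group[group["dose"] == 0]
        if control.empty:
            raise ValueError(f"cell line {cell_line!r} has no 0 Gy control records")
        pe = plating_efficiency(control["colonies"].sum(), control["cells_seeded"].sum())
        sf = group.apply(
            lambda r: survival_fraction(r["colonies"], r["cells_seeded"], pe), axis=1
        )
        with_sf = group.assign(sf=sf)
        doses = sorted(with_sf["dose"].unique())
        if len(doses) < 2:
            raise ValueError("survival curve needs >= 2 doses")
        table = (
            with_sf.groupby("dose", sort=True)["sf"]
            .agg(mean_sf="mean", sd_sf=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
            .reset_index()
        )
        entry: dict = {"plating_efficiency": pe, "table": table}
        if fit_lq:
            alpha, beta = fit_linear_quadratic(
                with_sf["dose"].to_numpy(), with_sf["sf"].to_numpy()
            )
            entry["lq_alpha"] = alpha
            entry["lq_beta"] = beta
        out[str(cell_line)] = entry
    return out


def apoptosis_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD total apoptotic fraction per cell line and time point."""
    missing = set(APOPTOSIS_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"apoptosis records missing column(s): {sorted(missing)}")
    totals = records.apply(
        lambda r: apoptosis_total(
            ApoptosisRecord(
                r["annexin_pos_pi_neg"], r["annexin_pos_pi_pos"],
                r["annexin_neg_pi_neg"], r["annexin_neg_pi_pos"], r["time_h"],
            )
        ),
        axis=1,
    )
    summary = (
        records.assign(total_apoptosis=totals)
        .groupby(["cell_line", "time_h"], sort=True)["total_apoptosis"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
        .reset_index()
    )
    return summary


def qpcr_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Relative expression 2^-dCT per target from replicate CT values."""
    missing = set(QPCR_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"qPCR records missing column(s): {sorted(missing)}")
    rows = []
    for target, group in records.groupby("target_id", sort=True):
        rows.append(
            (
                target,
                relative_expression_dct(
                    group["ct_target"].to_numpy(), group["ct_reference"].to_numpy()
                ),
                len(group),
            )
        )
    return pd.DataFrame(rows, columns=["target_id", "relative_expression", "n_replicates"])
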