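"""qPCR T/S telomere-length arithmetic and batch correction.

The relative-quantification workflow follows the standard Cawthon design:
telomere (T) and single-copy-gene 36B4 (S) reactions run on two separate
plates in identical well positions, each sample in triplicate.  A reference
DNA diluted threefold from 109.0 ng/uL down to 1.3 ng/uL gives each plate a
standard curve Cq = slope * log10(conc) + intercept, from which sample
concentrations are interpolated.  Amplification efficiency is
10^(-1/slope) - 1 (1.0 = perfect doubling).

Triplicates are averaged after an outlier rule: the single well farthest
from the triplicate median is dropped when it deviates by more than 0.5 Cq;
if the surviving wells' concentration CV still exceeds the threshold the
sample is flagged for repeat.  Inter-plate shifts are removed with a
normalization factor per plate — the control sample's grand-mean
concentration across plates divided by that plate's control mean — applied
multiplicatively to every sample concentration, which makes the final T/S
ratios invariant to rescaling any single plate.  When runs span batches,
T and S concentrations are batch-adjusted by linear regression (residual +
grand mean) before the final ratio; the same adjustment serves to correct
WGS-derived telomere-length estimates for sequencing run.

T/S ratios are relative telomere length; they are deliberately not rescaled
to base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "TSResult",
    "DEFAULT_STANDARD_CONCS",
    "fit_standard_curve",
    "average_triplicate",
    "compute_ts",
    "process_plates",
    "batch_adjust",
]

#: Default threefold dilution series of the reference DNA, ng/uL.
DEFAULT_STANDARD_CONCS = (109.0, 36.3, 12.1, 4.0, 1.3)

CQ_OUTLIER_THRESHOLD = 0.5  # cycles from triplicate median
CONC_CV_THRESHOLD = 0.15  # flag sample for repeat above this


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def interpolate(self, cq) -> np.ndarray:
        """Concentration(s) for the given Cq value(s)."""
        cq = np.asarray(cq, dtype=float)
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class TSResult:
    sample_id: str
    t_conc: float
    s_conc: float
    ts_ratio: float
    batch: str
    ts_ratio_adjusted: float | None = None
    flag: str = "ok"  # "ok" or "repeat"


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq against log10(concentration).

    Parameters are (conc ng/uL, Cq) pairs; at least three distinct
    concentrations are required.
    """
    concs = np.array([c for c, _ in standards], dtype=float)
    cqs = np.array([q for _, q in standards], dtype=float)
    if len(np.unique(concs)) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    x = np.log10(concs)
    slope, intercept = np.polyfit(x, cqs, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((cqs - fitted) ** 2))
    ss_tot = float(np.sum((cqs - cqs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        efficiency=float(10.0 ** (-1.0 / slope) - 1.0),
        r_squared=r2,
    )


def average_triplicate(
    cqs: Sequence[float],
    curve: StandardCurve,
    cq_outlier_threshold: float = CQ_OUTLIER_THRESHOLD,
    cv_threshold: float = CONC_CV_THRESHOLD,
) -> tuple[float, bool]:
    """Mean interpolated concentration of a replicate set, with outlier rule.

    Drops the single well farthest from the replicate median when it
    deviates by more than ``cq_outlier_threshold`` cycles; returns
    ``(mean_conc, needs_repeat)`` where ``needs_repeat`` is True when the
    surviving concentrations' CV still exceeds ``cv_threshold``.
    """
    cqs = np.asarray(cqs, dtype=float)
    if len(cqs) < 2:
        raise ValueError("need at least 2 replicate wells")
    dev = np.abs(cqs - np.median(cqs))
    worst = int(np.argmax(dev))
    if len(cqs) >= 3 and dev[worst] > cq_outlier_threshold:
        cqs = np.delete(cqs, worst)
    concs = curve.interpolate(cqs)
    mean = float(concs.mean())
    cv = float(concs.std(ddof=1) / mean) if mean > 0 else np.inf
    return mean, cv > cv_threshold


def compute_ts(
    sample_id: str,
    t_cqs: Sequence[float],
    s_cqs: Sequence[float],
    t_curve: StandardCurve,
    s_curve: StandardCurve,
    t_norm_factor: float = 1.0,
    s_norm_factor: float = 1.0,
    batch: str = "batch1",
) -> TSResult:
    """T/S ratio for one sample from its triplicate Cqs on the two plates.

    Concentrations are interpolated from each plate's standard curve,
    triplicate-averaged with the outlier rule, multiplied by the plate
    normalization factors, and divided (T over S).
    """
    t_conc, t_repeat = average_triplicate(t_cqs, t_curve)
    s_conc, s_repeat = average_triplicate(s_cqs, s_curve)
    t_conc *= t_norm_factor
    s_conc *= s_norm_factor
    return TSResult(
        sample_id=sample_id,
        t_conc=t_conc,
        s_conc=s_conc,
        ts_ratio=t_conc / s_conc,
        batch=batch,
        flag="repeat" if (t_repeat or s_repeat) else "ok",
    )


def batch_adjust(values, batch_labels) -> np.ndarray:
    """Remove batch main effects by linear regression.

    Regresses the values on batch indicators and returns residual + grand
    mean, so every batch mean maps to the grand mean exactly while
    within-batch variation is preserved.  A single batch is an identity
    transform (with a warning).  Each batch needs n >= 2.
    """
    values = np.asarray(values, dtype=float)
    batch_labels = np.asarray(batch_labels)
    if len(values) != len(batch_labels):
        raise ValueError("values and batch_labels must align")
    levels, counts = np.unique(batch_labels, return_counts=True)
    if len(levels) < 2:
        warnings.warn("single batch; batch adjustment is an identity transform")
        return values.copy()
    if counts.min() < 2:
        raise ValueError("every batch needs n >= 2")
    grand = values.mean()
    adjusted = np.empty_like(values)
    # OLS on batch dummies fits each batch its own mean; residual + grand mean
    for lev in levels:
        mask = batch_labels == lev
        adjusted[mask] = values[mask] - values[mask].mean() + grand
    return adjusted


def _plate_curve(plate: pd.DataFrame) -> StandardCurve:
    std = plate[plate["role"] == "standard"]
    if std.empty:
        raise ValueError(f"plate {plate['plate_id'].iloc[0]!r} has no standard wells")
    return fit_standard_curve(list(zip(std["conc"], std["cq"])))


def process_plates(
    wells: pd.DataFrame,
    apply_batch_adjustment: bool = True,
    reference: str = "control",
) -> pd.DataFrame:
    """Full plate-table workflow: curves, triplicates, normalization, batches.

    ``wells`` columns: ``plate_id``, ``assay`` ("T" or "S"), ``sample_id``,
    ``role`` ("sample" / "standard" / "control"), ``cq``, ``batch``, and
    ``conc`` (standards only).  Control wells carry ``role == "control"``;
    every plate must include the control in replicate.

    ``reference`` sets the normalization factor's anchor.  The default,
    ``"control"``, expresses every concentration relative to the plate's
    control mean, which makes the resulting T/S ratios exactly invariant to
    rescaling any single plate (the ratios are then relative to the control
    DNA's own T/S, the usual relative-quantification convention).
    ``"grand_mean"`` instead anchors each plate to the control's grand mean
    across that assay's plates, keeping concentrations on the ng/uL scale at
    the cost of exact single-plate scale invariance.

    Returns one row per sample with normalized T and S concentrations, the
    T/S ratio, the batch label, the repeat flag and — when at least two
    batches are present — the batch-adjusted ratio (T and S concentrations
    adjusted separately before the final ratio).
    """
    if reference not in ("control", "grand_mean"):
        raise ValueError(f"unknown normalization reference {reference!r}")
    curves: dict[str, StandardCurve] = {}
    control_means: dict[str, float] = {}
    for plate_id, plate in wells.groupby("plate_id"):
        curves[plate_id] = _plate_curve(plate)
        ctrl = plate[plate["role"] == "control"]
        if ctrl.empty:
            raise ValueError(f"control sample missing on plate {plate_id!r}")
        control_means[plate_id] = float(
            curves[plate_id].interpolate(ctrl["cq"].to_numpy()).mean()
        )

    assay_of_plate = wells.groupby("plate_id")["assay"].first()
    norm_factors: dict[str, float] = {}
    for assay in ("T", "S"):
        plate_ids = [p for p in curves if assay_of_plate[p] == assay]
        if not plate_ids:
            raise ValueError(f"no {assay} plates in input")
        anchor = (
            1.0
            if reference == "control"
            else float(np.mean([control_means[p] for p in plate_ids]))
        )
        for p in plate_ids:
            norm_factors[p] = anchor / control_means[p]

    samples = wells[wells["role"] == "sample"]
    rows: list[dict] = []
    for sid in samples["sample_id"].unique():
        sub = samples[samples["sample_id"] == sid]
        per_assay: dict[str, tuple[float, bool, str]] = {}
        for assay in ("T", "S"):
            part = sub[sub["assay"] == assay]
            if part.empty:
                raise ValueError(f"sample {sid!r} missing from {assay} plate")
            plate_id = part["plate_id"].iloc[0]
            conc, repeat = average_triplicate(part["cq"].to_numpy(), curves[plate_id])
            per_assay[assay] = (
                conc * norm_factors[plate_id],
                repeat,
                str(part["batch"].iloc[0]),
            )
        t_conc, t_rep, batch = per_assay["T"]
        s_conc, s_rep, _ = per_assay["S"]
        rows.append(
            {
                "sample_id": sid,
                "t_conc": t_conc,
                "s_conc": s_conc,
                "ts_ratio": t_conc / s_conc,
                "batch": batch,
                "flag": "repeat" if (t_rep or s_rep) else "ok",
            }
        )
    out = pd.DataFrame(rows)

    if apply_batch_adjustment and out["batch"].nunique() >= 2:
        t_adj = batch_adjust(out["t_conc"].to_numpy(), out["batch"].to_numpy())
        s_adj = batch_adjust(out["s_conc"].to_numpy(), out["batch"].to_numpy())
        out["ts_ratio_adjusted"] = t_adj / s_adj
    else:
        out["ts_ratio_adjusted"] = out["ts_ratio"]
    return out
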