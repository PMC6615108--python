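"""Housekeeping-gene normalization and fold change.

Per well, the relative expression of a gene is its background-corrected
signal divided by the geometric mean of the well's housekeeping genes (HKG);
the fold change (FC) divides that by the median relative expression of the
untreated negative-control wells, gene by gene. A well-chosen HKG set makes
FC invariant to per-well scale effects (sample input, pipetting, plate
position).

HKG stability is assessed on the FC scale: a stable HKG stays inside the
[0.8, 1.2] interval (20% tolerance) over the sample wells. Unstable HKG are
removed one at a time — worst |log FC| excursion beyond the interval first,
recomputing FC after each removal because the geometric mean changes — until
the remaining set is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background_loq import CorrectedMatrix
from .errors import StabilityError, StageError, ValidationError
from .plate_io import ROLE_NEGATIVE, ROLE_SAMPLE

DEFAULT_FC_RANGE = (0.8, 1.2)
MIN_NEGATIVE_WELLS_ADVISED = 6

STAGES = ("raw", "corrected", "relative", "fold_change")


@dataclass
class ExpressionMatrix:
    """Wells x genes values at a named stage of the transformation chain."""

    stage: str
    values: pd.DataFrame
    lineage: "ExpressionMatrix | None" = None
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class HKGStabilityReport:
    retained: list[str]
    removed: list[tuple[str, int, float]]  # (hkg, iteration, offending FC extremum)
    condition_summary: pd.DataFrame  # per HKG x condition FC summary


def geometric_mean_hkg(corrected: CorrectedMatrix | pd.DataFrame, hkg_names: list[str]) -> pd.Series:
    """Per-well geometric mean of the HKG corrected signals.

    A well with any HKG at 0 yields 0 (it should have been removed by the
    LOQ rule already) and is reported with a warning.
    """
    if not hkg_names:
        raise ValidationError("hkg_names must be nonempty")
    values = corrected.values if isinstance(corrected, CorrectedMatrix) else corrected
    hk = values[list(hkg_names)].astype(float)
    if hk.isna().any().any():
        bad = list(hk.index[hk.isna().any(axis=1)])
        raise ValidationError(f"wells missing HKG values: {bad}")
    with np.errstate(divide="ignore"):
        # skipna=False: any zero HKG must pull the whole geometric mean to 0
        gm = np.exp(np.log(hk.where(hk > 0)).mean(axis=1, skipna=False)).fillna(0.0)
    zero = list(gm.index[gm == 0])
    if zero:
        warnings.warn(f"wells with an HKG signal of 0 (geometric mean 0): {zero}")
        gm[zero] = 0.0
    return gm


def relative_expression(
    corrected: CorrectedMatrix | pd.DataFrame, geomean: pd.Series
) -> ExpressionMatrix:
    """Corrected signal divided by the well's HKG geometric mean."""
    values = corrected.values if isinstance(corrected, CorrectedMatrix) else corrected
    if (geomean.loc[values.index] == 0).any():
        bad = list(values.index[geomean.loc[values.index] == 0])
        raise StageError(f"geometric mean is 0 in retained well(s) {bad}")
    return ExpressionMatrix(stage="relative", values=values.div(geomean, axis=0))


def fold_change(
    relative: ExpressionMatrix,
    annotations: pd.DataFrame,
    min_negative_warn: int = MIN_NEGATIVE_WELLS_ADVISED,
) -> ExpressionMatrix:
    """Relative expression divided by the per-gene median of negative controls.

    By construction the median negative-control FC of every gene is exactly
    1. Genes whose negative-control median is 0 cannot be expressed as FC and
    are dropped (listed in ``missing_genes``).
    """
    neg = [w for w in relative.values.index if annotations.at[w, "role"] == ROLE_NEGATIVE]
    if not neg:
        raise StageError("no negative-control wells survive QC; fold change undefined")
    if len(neg) < min_negative_warn:
        warnings.warn(
            f"only {len(neg)} negative-control wells; at least {min_negative_warn} "
            "are advised for a stable FC baseline"
        )
    med = relative.values.loc[neg].median(axis=0)
    missing = list(med.index[med == 0])
    keep = [g for g in relative.values.columns if g not in missing]
    if missing:
        warnings.warn(f"negative-control median is 0 for gene(s) {missing}; FC not computed")
    fc = relative.values[keep].div(med[keep], axis=1)
    return ExpressionMatrix(stage="fold_change", values=fc, lineage=relative, missing_genes=missing)


def _excursion(fc: pd.Series, lo: float, hi: float) -> float:
    """Largest |log FC| overshoot beyond [lo, hi]; 0 when all inside."""
    with np.errstate(divide="ignore"):
        logfc = np.log(fc.astype(float))
    over = np.maximum(logfc - np.log(hi), 0.0)
    under = np.maximum(np.log(lo) - logfc, 0.0)
    return float(np.maximum(over, under).max()) if len(fc) else 0.0


def compute_fc(
    corrected: CorrectedMatrix | pd.DataFrame,
    annotations: pd.DataFrame,
    hkg_names: list[str],
    min_negative_warn: int = MIN_NEGATIVE_WELLS_ADVISED,
) -> ExpressionMatrix:
    """Convenience chain: geometric mean -> relative expression -> fold change."""
    gm = geometric_mean_hkg(corrected, hkg_names)
    rel = relative_expression(corrected, gm)
    return fold_change(rel, annotations, min_negative_warn=min_negative_warn)


def hkg_stability_filter(
    corrected: CorrectedMatrix | pd.DataFrame,
    annotations: pd.DataFrame,
    hkg_names: list[str],
    fc_range: tuple[float, float] = DEFAULT_FC_RANGE,
    tolerated_fraction: float = 0.0,
    exclude_wells: tuple[str, ...] = (),
) -> HKGStabilityReport:
    """Iteratively remove unstable HKG until the remaining set is stable.

    An HKG is unstable when more than ``tolerated_fraction`` of its
    sample-well FC values fall outside ``fc_range`` (default: any single
    well). Each iteration removes the single worst offender (largest |log FC|
    excursion beyond the interval) and recomputes FC with the reduced set.
    ``exclude_wells`` (e.g. wells of cytotoxicity-flagged conditions in
    screening mode) are ignored when judging stability. Raises
    StabilityError if the last remaining HKG is still unstable.
    """
    if not hkg_names:
        raise ValidationError("hkg_names must be nonempty")
    lo, hi = fc_range
    current = list(hkg_names)
    removed: list[tuple[str, int, float]] = []
    iteration = 0
    values = corrected.values if isinstance(corrected, CorrectedMatrix) else corrected
    sample_wells = [
        w
        for w in values.index
        if annotations.at[w, "role"] == ROLE_SAMPLE and w not in set(exclude_wells)
    ]
    while True:
        iteration += 1
        fc = compute_fc(corrected, annotations, current, min_negative_warn=0)
        sub = fc.values.loc[[w for w in sample_wells if w in fc.values.index]]
        offenders = {}
        for h in current:
            fcs = sub[h]
            outside = ((fcs < lo) | (fcs > hi)).mean() if len(fcs) else 0.0
            if outside > tolerated_fraction:
                offenders[h] = _excursion(fcs, lo, hi)
        if not offenders:
            break
        if len(current) == 1:
            raise StabilityError(
                f"last remaining HKG {current[0]!r} is still outside the "
                f"[{lo}, {hi}] FC interval; re-optimize the assay / HKG panel"
            )
        worst = max(sorted(offenders), key=lambda h: offenders[h])
        fcs = sub[worst]
        extremum = float(fcs.loc[(np.log(fcs.astype(float))).abs().idxmax()])
        removed.append((worst, iteration, extremum))
        current.remove(worst)

    fc = compute_fc(corrected, annotations, current, min_negative_warn=0)
    rows = []
    sub = fc.values.loc[[w for w in sample_wells if w in fc.values.index]]
    for h in current:
        grouped = sub[h].groupby(
            [annotations.loc[sub.index, "compound"], annotations.loc[sub.index, "concentration"]]
        )
        for (cpd, dose), vals in grouped:
            rows.append(
                {
                    "hkg": h,
                    "compound": cpd,
                    "concentration": dose,
                    "fc_mean": float(vals.mean()),
                    "fc_min": float(vals.min()),
                    "fc_max": float(vals.max()),
                }
            )
    summary = pd.DataFrame(
        rows, columns=["hkg", "compound", "concentration", "fc_mean", "fc_min", "fc_max"]
    )
    return HKGStabilityReport(retained=current, removed=removed, condition_summary=summary)
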