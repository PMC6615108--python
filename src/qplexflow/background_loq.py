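"""Background statistics, background correction and limits of quantification.

Background wells carry no RNA sample and measure per-analyte technical noise.
Per gene, the mean and (sample) standard deviation of their MFI define the
limits of quantification LOQ_k = mean + k * SD for k in {3, 5, 10}; LOQ_10 is
the working lower limit of the assay's linear range. The mean is subtracted
from every sample/control reading (negative results clamped to zero), and any
well whose background-corrected housekeeping-gene signal falls below LOQ_10
is removed — the HKG signal of such a well is too close to noise to
normalize against. Non-HKG genes below LOQ are retained: weak disease-gene
signals can still inform the dose-response fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StageError, ValidationError
from .plate_io import ROLE_BACKGROUND, ROLE_NEGATIVE, AnnotatedPlate

LOQ_KS = (3, 5, 10)
DEFAULT_LOQ_K = 10
MIN_BACKGROUND_WELLS_ADVISED = 6


@dataclass
class BackgroundStats:
    """Per-gene background mean/SD and derived LOQ thresholds."""

    table: pd.DataFrame  # index gene; columns bg_mean, bg_sd, n_bg, loq_3, loq_5, loq_10
    outlier_flags: list[tuple[str, str, float]] = field(default_factory=list)  # (well, gene, value)
    warnings: list[str] = field(default_factory=list)

    def loq(self, k: int) -> pd.Series:
        return self.table["bg_mean"] + k * self.table["bg_sd"]

    @property
    def bg_mean(self) -> pd.Series:
        return self.table["bg_mean"]

    @property
    def bg_sd(self) -> pd.Series:
        return self.table["bg_sd"]


@dataclass
class RemovalRecord:
    well_id: str
    hkg: str
    value: float
    reason: str  # below_loq | hkg_missing


@dataclass
class CorrectedMatrix:
    """Background-corrected wells x genes matrix (sample + negative-control wells)."""

    values: pd.DataFrame
    stats: BackgroundStats
    removed_wells: list[RemovalRecord] = field(default_factory=list)

    @property
    def wells(self) -> list[str]:
        return list(self.values.index)


def background_stats(plate: AnnotatedPlate) -> BackgroundStats:
    """Mean/SD of background-well MFI per gene (bead-filtered entries excluded).

    Requires >= 2 surviving background wells per gene (sample SD needs two);
    warns when fewer than 6 background wells are available, and flags (but
    does not remove) background readings more than 3 SD from the gene mean —
    removing a deviating background well is a template-level decision.
    """
    bg_wells = plate.wells_with_role(ROLE_BACKGROUND)
    if not bg_wells:
        raise StageError("no background wells on the plate")
    bg = plate.mfi.loc[bg_wells]
    n_bg = bg.notna().sum(axis=0)
    if (n_bg < 2).any():
        bad = list(n_bg.index[n_bg < 2])
        raise StageError(f"fewer than 2 background readings for gene(s) {bad}; SD undefined")
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    table = pd.DataFrame({"bg_mean": mean, "bg_sd": sd, "n_bg": n_bg})
    for k in LOQ_KS:
        table[f"loq_{k}"] = mean + k * sd
    msgs = []
    if len(bg_wells) < MIN_BACKGROUND_WELLS_ADVISED:
        msg = (
            f"only {len(bg_wells)} background wells; at least "
            f"{MIN_BACKGROUND_WELLS_ADVISED} are advised for a stable LOQ estimate"
        )
        warnings.warn(msg)
        msgs.append(msg)
    flags = []
    for g in bg.columns:
        if sd[g] > 0:
            dev = (bg[g] - mean[g]).abs() > 3 * sd[g]
            flags.extend((w, g, float(bg.at[w, g])) for w in bg.index[dev])
    return BackgroundStats(table=table, outlier_flags=flags, warnings=msgs)


def background_correct(plate: AnnotatedPlate, stats: BackgroundStats) -> CorrectedMatrix:
    """Subtract the gene's background mean; clamp negatives to zero.

    Background wells themselves are excluded from the corrected matrix (they
    never enter downstream sample stages).
    """
    missing = [g for g in plate.genes if g not in stats.table.index]
    if missing:
        raise ValidationError(f"background stats missing for gene(s) {missing}")
    keep = plate.annotations.index[plate.annotations["role"] != ROLE_BACKGROUND]
    corrected = (plate.mfi.loc[keep] - stats.bg_mean[plate.genes]).clip(lower=0.0)
    return CorrectedMatrix(values=corrected, stats=stats)


def remove_wells_below_loq(
    corrected: CorrectedMatrix,
    hkg_names: list[str],
    k: int = DEFAULT_LOQ_K,
) -> CorrectedMatrix:
    """Drop every well with at least one HKG below LOQ_k.

    On the corrected scale the raw-vs-LOQ comparison ``raw < mean + k*SD``
    becomes ``corrected < k*SD`` (strict). Wells whose HKG reading was itself
    discarded upstream (NaN) are removed too — they cannot be normalized.
    Only wells are ever removed, never genes.
    """
    if not hkg_names:
        raise ValidationError("hkg_names must be nonempty")
    cut = k * corrected.stats.bg_sd
    removed: list[RemovalRecord] = []
    keep_wells = []
    for w in corrected.values.index:
        verdict = None
        for h in hkg_names:
            v = corrected.values.at[w, h]
            if np.isnan(v):
                verdict = RemovalRecord(w, h, float("nan"), "hkg_missing")
                break
            if v < cut[h]:
                verdict = RemovalRecord(w, h, float(v), "below_loq")
                break
        if verdict is None:
            keep_wells.append(w)
        else:
            removed.append(verdict)
    if not keep_wells:
        raise StageError("every well fails the HKG LOQ rule; plate unusable")
    return CorrectedMatrix(
        values=corrected.values.loc[keep_wells],
        stats=corrected.stats,
        removed_wells=corrected.removed_wells + removed,
    )


def hkg_linearity(
    corrected: CorrectedMatrix,
    annotations: pd.DataFrame,
    hkg_names: list[str],
    k: int = DEFAULT_LOQ_K,
    saturation_mfi: float | None = None,
) -> pd.DataFrame:
    """OLS line of corrected HKG signal vs. cell count over negative controls.

    An assay-optimization diagnostic: within the linear range the corrected
    signal should be proportional to the number of lysed cells. Points below
    LOQ_k (and, if a cap is given, saturated points) are flagged. Returns one
    row per HKG with slope, intercept, r_squared and flag counts; empty frame
    (with a warning) when fewer than 3 distinct cell counts are available.
    """
    neg = [
        w
        for w in corrected.values.index
        if annotations.at[w, "role"] == ROLE_NEGATIVE and annotations.at[w, "cell_count"] is not None
    ]
    counts = pd.Series(
        [annotations.at[w, "cell_count"] for w in neg], index=neg, dtype=float
    ).dropna()
    cols = ["hkg", "slope", "intercept", "r_squared", "n", "n_below_loq", "n_saturated"]
    if counts.nunique() < 3:
        warnings.warn("fewer than 3 distinct cell counts among negative controls; "
                      "linearity diagnostic skipped")
        return pd.DataFrame(columns=cols)
    rows = []
    for h in hkg_names:
        y = corrected.values.loc[counts.index, h].astype(float)
        res = sps.linregress(counts.values, y.values)
        below = int((y < k * corrected.stats.bg_sd[h]).sum())
        sat = 0
        if saturation_mfi is not None:
            sat = int((y + corrected.stats.bg_mean[h] >= saturation_mfi).sum())
        rows.append(
            {
                "hkg": h,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
                "n": int(len(y)),
                "n_below_loq": below,
                "n_saturated": sat,
            }
        )
    return pd.DataFrame(rows, columns=cols)
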