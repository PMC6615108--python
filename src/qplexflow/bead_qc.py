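"""Bead-count QC.

A Luminex well reports, per analyte, the median fluorescence over the
individual beads captured for that analyte. When the bead count drops (sample
viscosity, washing, carryover) the reported median becomes unstable. Two
things live here:

* the production-time filter that discards (well, gene) readings backed by
  fewer beads than a threshold (default 37);
* the optimisation-time stability analysis that justifies such a threshold:
  subsample the bead-level fluorescence at sizes 10..50, measure the percent
  deviation of the subsample median from the full-set median, fit a
  continuous hockey-stick (sloped segment + flat plateau) to the mean
  absolute deviation per gene, and take a high quantile of the per-gene
  breakpoints as the recommended plate-wide threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, StageError
from .plate_io import AnnotatedPlate, DiscardRecord

DEFAULT_BEAD_THRESHOLD = 37
DEFAULT_SUBSAMPLE_SIZES = (10, 20, 30, 40, 50)
DEFAULT_SUBSAMPLE_REPS = 100


@dataclass
class BeadFilterReport:
    threshold: int
    removed: list[tuple[str, str, int]]  # (well_id, gene, bead_count)


@dataclass
class BreakpointFit:
    gene: str
    breakpoint: float
    slope: float
    plateau: float
    sse: float
    degenerate: bool = False


def filter_by_bead_count(
    plate: AnnotatedPlate, threshold: int = DEFAULT_BEAD_THRESHOLD
) -> tuple[AnnotatedPlate, BeadFilterReport]:
    """Mask MFI entries whose bead count is strictly below ``threshold``.

    Entries with ``bead_count >= threshold`` are untouched. Removed entries
    are listed in the report and appended to the plate's discard log.
    """
    if threshold < 1:
        raise ValueError("bead threshold must be >= 1")
    out = plate.copy()
    low = (out.bead_counts < threshold) & out.mfi.notna()
    ii, jj = np.where(low.values)
    removed = [
        (str(low.index[i]), str(low.columns[j]), int(out.bead_counts.iat[i, j]))
        for i, j in zip(ii, jj)
    ]
    out.mfi = out.mfi.mask(low)
    out.discarded.extend(DiscardRecord(w, g, "low_bead_count") for w, g, _ in removed)
    return out, BeadFilterReport(threshold=threshold, removed=removed)


def subsample_deviation(
    bead_signals: dict[tuple[str, str], np.ndarray],
    sizes=DEFAULT_SUBSAMPLE_SIZES,
    reps: int = DEFAULT_SUBSAMPLE_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent deviation of subsample medians from the full-set median.

    For each (gene, well) bead array, each subsample size and each of
    ``reps`` replicates, draw that many beads without replacement and compute

        %dev = (median(subsample) - median(all beads)) / median(all beads) * 100.

    Returns a tidy frame with one row per (gene, well, size) holding the
    replicate-averaged signed deviation and the replicate-averaged absolute
    deviation (used for the breakpoint fit; signed means can cancel).
    (gene, well) combinations shorter than a requested size, or with
    full-set median 0, are skipped with a warning. Keys are processed in
    sorted order so a seed fully determines the draws.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, well in sorted(bead_signals):
        # sorted copy: medians are order-free and this makes the result exactly
        # invariant to the input ordering of the bead array under a fixed seed
        arr = np.sort(np.asarray(bead_signals[(gene, well)], dtype=float))
        full_median = float(np.median(arr))
        if full_median == 0:
            warnings.warn(f"({gene}, {well}): full-set median is 0, skipped")
            continue
        for size in sizes:
            if len(arr) < size:
                warnings.warn(f"({gene}, {well}): only {len(arr)} beads, size {size} skipped")
                continue
            devs = np.empty(reps)
            for r in range(reps):
                sub = arr[rng.choice(len(arr), size=size, replace=False)]
                devs[r] = (np.median(sub) - full_median) / full_median * 100.0
            rows.append(
                {
                    "gene": gene,
                    "well_id": well,
                    "n_sub": size,
                    "dev_pct": float(devs.mean()),
                    "abs_dev_pct": float(np.abs(devs).mean()),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "well_id", "n_sub", "dev_pct", "abs_dev_pct"])


def gene_mean_abs_deviation(dev: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute %deviation per gene and subsample size, across wells."""
    return (
        dev.groupby(["gene", "n_sub"], as_index=False)["abs_dev_pct"]
        .mean()
        .sort_values(["gene", "n_sub"], ignore_index=True)
    )


def fit_breakpoint(n, y, gene: str = "", grid_step: float = 0.1) -> BreakpointFit:
    """Continuous hockey-stick fit: sloped first segment, flat plateau after.

    The model is ``y = plateau + slope * min(n - bp, 0)``; for each candidate
    breakpoint on a dense grid over [min(n), max(n)] the two linear
    parameters are solved by least squares, and the breakpoint minimizing the
    SSE is kept (ties -> smallest breakpoint). With (near-)flat input the fit
    is flagged degenerate: there is no elbow to locate.
    """
    n = np.asarray(n, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(n) < 4:
        raise FitError("breakpoint fit needs at least 4 points")
    if not np.all(np.diff(n) > 0):
        raise FitError("subsample sizes must be strictly increasing")
    grid = np.arange(n[0], n[-1] + grid_step / 2, grid_step)
    best = None
    for bp in grid:
        x2 = np.minimum(n - bp, 0.0)
        design = np.column_stack([np.ones_like(n), x2])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(bp), float(coef[1]), float(coef[0]))
    sse, bp, slope, plateau = best
    scale = max(1.0, float(np.abs(y).max()))
    degenerate = float(np.ptp(y)) < 1e-9 * scale or abs(slope) < 1e-9
    return BreakpointFit(gene=gene, breakpoint=bp, slope=slope, plateau=plateau,
                         sse=sse, degenerate=degenerate)


def threshold_quantile(fits: list[BreakpointFit], q: float = 0.95) -> float:
    """q-quantile (linear interpolation) of the non-degenerate breakpoints."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    bps = [f.breakpoint for f in fits if not f.degenerate]
    if not bps:
        raise StageError("all breakpoint fits are degenerate; no threshold recommendation")
    return float(np.quantile(bps, q))
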