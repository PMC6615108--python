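"""Synthetic plate generator with known ground truth.

Emulates a 96-well bDNA/Luminex run: a plate-layout template, a raw table of
per-well, per-gene median fluorescence intensities (MFI) and bead counts,
and optional bead-level fluorescence arrays — all derived from an explicit
``SyntheticTruth`` so every pipeline stage can be checked against what was
planted:

* per gene x compound dose-response parameters (b, c, e) on the fold-change
  scale (absent = null response, FC 1 at every dose);
* per-gene additive background (mean + SD) — background wells carry a fixed
  standardized deviation pattern, so their sample mean and SD reproduce the
  nominal values exactly even in the noise-free case;
* multiplicative log-normal MFI noise (positive support, as fluorescence);
* planted QC violations: low-bead (well, gene) entries, wells with an HKG
  pushed below LOQ_10, HKG fold-change excursions, and cytotoxic compounds
  that scale every transcript down past an onset dose.

The layout is deterministic (background wells first, then negative controls,
then compounds in order with ascending doses, row-major from A01), so tests
can map a planted condition to its well coordinate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import log_logistic
from .plate_io import (
    ROLE_BACKGROUND,
    ROLE_NEGATIVE,
    ROLE_SAMPLE,
    AnnotatedPlate,
    PlateTemplate,
    RawPlate,
)

_ROWS = "ABCDEFGH"
DEFAULT_DOSES = tuple(0.1 * 10 ** (k / 2) for k in range(6))  # half-log ladder


def _well_name(i: int) -> str:
    return f"{_ROWS[i // 12]}{i % 12 + 1:02d}"


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated plate."""

    title: str
    genes: list[str]
    hkg: list[str]
    compounds: list[str]
    doses: dict[str, tuple[float, ...]]
    dr_params: dict[tuple[str, str], tuple[float, float, float]]  # (gene, cpd) -> (b, c, e)
    baseline: dict[str, float]  # corrected signal of an untreated well
    bg_mean: dict[str, float]
    bg_sd: dict[str, float]
    noise_sd: float = 0.0
    bead_count_range: tuple[int, int] = (45, 75)
    n_background: int = 6
    n_negative: int = 6
    cell_count: int = 2500
    timepoint: str = "24h"
    cell_line: str = "CELL_C"
    cytotoxic: dict[str, tuple[float, float]] = field(default_factory=dict)  # cpd -> (onset, viability)
    unstable_hkg: dict[tuple[str, str, float], float] = field(default_factory=dict)  # (hkg, cpd, dose) -> factor
    low_bead: list[tuple[str, float, str, int]] = field(default_factory=list)  # (cpd, dose, gene, count)
    low_hkg: list[tuple[str, float, str, float]] = field(default_factory=list)  # (cpd, dose, hkg, frac of 10*SD)
    seed: int = 0

    @property
    def all_genes(self) -> list[str]:
        return self.genes + self.hkg

    def fold_effect(self, gene: str, compound: str, dose: float) -> float:
        par = self.dr_params.get((gene, compound))
        if par is None:
            return 1.0
        b, c, e = par
        return float(log_logistic(np.array([dose]), b, c, e)[0])

    def layout(self) -> pd.DataFrame:
        """Deterministic well annotations: background, negatives, then samples."""
        total = self.n_background + self.n_negative + sum(
            len(self.doses[cpd]) for cpd in self.compounds
        )
        if total > 96:
            raise ValueError(f"layout needs {total} wells; a 96-well plate has 96")
        rows = []
        i = 0
        for _ in range(self.n_background):
            rows.append({"well_id": _well_name(i), "role": ROLE_BACKGROUND, "compound": None,
                         "concentration": 0.0})
            i += 1
        for _ in range(self.n_negative):
            rows.append({"well_id": _well_name(i), "role": ROLE_NEGATIVE, "compound": None,
                         "concentration": 0.0})
            i += 1
        for cpd in self.compounds:
            for dose in self.doses[cpd]:
                rows.append({"well_id": _well_name(i), "role": ROLE_SAMPLE, "compound": cpd,
                             "concentration": float(dose)})
                i += 1
        df = pd.DataFrame(rows).set_index("well_id")
        df["cell_count"] = self.cell_count
        df["timepoint"] = self.timepoint
        df["cell_line"] = self.cell_line
        df.loc[df["role"] == ROLE_BACKGROUND, ["cell_count", "timepoint", "cell_line"]] = None
        return df

    def well_of(self, compound: str, dose: float) -> str:
        lay = self.layout()
        hit = lay.index[(lay["compound"] == compound) & (lay["concentration"] == dose)]
        if len(hit) != 1:
            raise KeyError(f"no unique well for {compound} @ {dose}")
        return hit[0]


def _bg_pattern(n: int) -> np.ndarray:
    """Fixed symmetric pattern with mean 0 and sample SD exactly 1."""
    v = np.linspace(-1.0, 1.0, n)
    return v / v.std(ddof=1)


@dataclass
class SimulatedPlate:
    truth: SyntheticTruth
    template: PlateTemplate
    raw: RawPlate
    plate: AnnotatedPlate
    template_path: Path | None = None
    raw_path: Path | None = None


def simulate_plate(truth: SyntheticTruth, out_dir: str | Path | None = None) -> SimulatedPlate:
    """Render the truth into template + raw tables (and optionally files).

    Sample/negative wells: MFI = (bg_mean + baseline * effect) * noise with
    effect = dose-response fold effect x cytotoxic viability x planted HKG
    excursion, and log-normal noise exp(noise_sd * N(0,1)). Background wells
    carry the fixed standardized pattern (no noise). Written files parse
    back, through plate_io, to the exact in-memory matrices.
    """
    rng = np.random.default_rng(truth.seed)
    lay = truth.layout()
    genes = truth.all_genes
    mfi = pd.DataFrame(index=lay.index, columns=pd.Index(genes, name="gene"), dtype=float)
    pat = _bg_pattern(truth.n_background)

    bg_wells = lay.index[lay["role"] == ROLE_BACKGROUND]
    for g in genes:
        mfi.loc[bg_wells, g] = truth.bg_mean[g] + truth.bg_sd[g] * pat

    for w in lay.index[lay["role"] != ROLE_BACKGROUND]:
        role = lay.at[w, "role"]
        cpd = lay.at[w, "compound"]
        dose = float(lay.at[w, "concentration"])
        viability = 1.0
        if role == ROLE_SAMPLE and cpd in truth.cytotoxic:
            onset, viab = truth.cytotoxic[cpd]
            if dose >= onset:
                viability = viab
        for g in genes:
            effect = 1.0
            if role == ROLE_SAMPLE:
                if g in truth.hkg:
                    effect = truth.unstable_hkg.get((g, cpd, dose), 1.0)
                else:
                    effect = truth.fold_effect(g, cpd, dose)
                effect *= viability
            noise = float(np.exp(truth.noise_sd * rng.standard_normal())) if truth.noise_sd else 1.0
            mfi.at[w, g] = (truth.bg_mean[g] + truth.baseline[g] * effect) * noise

    lo, hi = truth.bead_count_range
    beads = pd.DataFrame(
        rng.integers(lo, hi + 1, size=mfi.shape), index=mfi.index, columns=mfi.columns
    )
    for cpd, dose, g, count in truth.low_bead:
        beads.at[truth.well_of(cpd, dose), g] = count
    for cpd, dose, h, frac in truth.low_hkg:
        w = truth.well_of(cpd, dose)
        mfi.at[w, h] = truth.bg_mean[h] + frac * 10.0 * truth.bg_sd[h]

    annotations = lay.copy()
    template = PlateTemplate(
        title=truth.title, annotations=annotations, hkg_names=list(truth.hkg), raw_file="raw.csv"
    )
    raw = RawPlate(mfi=mfi, bead_counts=beads)
    plate = AnnotatedPlate(
        title=truth.title,
        annotations=annotations,
        mfi=mfi.copy(),
        bead_counts=beads.copy(),
        hkg_names=list(truth.hkg),
    )
    tpath = rpath = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tpath = out_dir / "template.xlsx"
        rpath = out_dir / "raw.csv"
        _write_template(template, tpath)
        _write_raw(raw, rpath)
    return SimulatedPlate(truth=truth, template=template, raw=raw, plate=plate,
                          template_path=tpath, raw_path=rpath)


def _write_template(template: PlateTemplate, path: Path) -> None:
    import openpyxl

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Plate"
    ws.cell(row=1, column=1, value=template.title)
    header = ["Well", "Compound", "Concentration", "Cell_count", "Timepoint", "Cell_line"]
    for j, h in enumerate(header, start=1):
        ws.cell(row=2, column=j, value=h)
    for i, (well, rec) in enumerate(template.annotations.iterrows(), start=3):
        compound = rec["compound"]
        if rec["role"] == ROLE_BACKGROUND:
            compound = "background"
        vals = [well, compound, rec["concentration"], rec["cell_count"],
                rec["timepoint"], rec["cell_line"]]
        for j, v in enumerate(vals, start=1):
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                ws.cell(row=i, column=j, value=v)
    hs = wb.create_sheet("HKG")
    for i, h in enumerate(template.hkg_names, start=1):
        hs.cell(row=i, column=1, value=h)
    if template.raw_file:
        rs = wb.create_sheet("Rawdata")
        rs.cell(row=1, column=1, value=template.raw_file)
    wb.save(path)


def _write_raw(raw: RawPlate, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "gene", "mfi", "bead_count"])
        for w in raw.mfi.index:
            for g in raw.mfi.columns:
                writer.writerow([w, g, repr(float(raw.mfi.at[w, g])), int(raw.bead_counts.at[w, g])])


def make_truth(
    seed: int = 0,
    n_genes: int = 20,
    n_hkg: int = 2,
    n_compounds: int = 10,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    noise_sd: float = 0.05,
    effect_fraction: float = 0.5,
    strong_c: float = 0.2,
    title: str = "synthetic screening plate",
    **overrides,
) -> SyntheticTruth:
    """Default study conditions: a screening plate shaped like a typical
    10-compound x 6-dose run with 20 target genes and 2 HKG, 6 background and
    6 negative-control wells, half-log dose ladder, 5% multiplicative noise.

    Roughly half the gene x compound pairs respond (effect_fraction); of the
    responders, 75% are suppressions (c drawn around ``strong_c``) and 25%
    inductions (c in [1.5, 3]); inflection doses fall inside the tested
    ladder. Everything is drawn from a single seeded generator.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    hkg = [f"HKG{i + 1:02d}" for i in range(n_hkg)]
    compounds = [f"CPD{i + 1:02d}" for i in range(n_compounds)]
    dr = {}
    for cpd in compounds:
        for g in genes:
            if rng.random() < effect_fraction:
                b = float(rng.uniform(0.7, 2.0))
                if rng.random() < 0.75:
                    c = float(np.clip(rng.normal(strong_c, 0.05), 0.02, 0.45))
                else:
                    c = float(rng.uniform(1.6, 3.0))
                e = float(np.log(rng.uniform(doses[1], doses[-2])))
                dr[(g, cpd)] = (b, c, e)
    baseline = {g: float(rng.uniform(2000, 8000)) for g in genes}
    baseline.update({h: float(rng.uniform(3000, 6000)) for h in hkg})
    bg_mean = {g: float(rng.uniform(50, 150)) for g in genes + hkg}
    bg_sd = {g: float(rng.uniform(5, 15)) for g in genes + hkg}
    truth = SyntheticTruth(
        title=title,
        genes=genes,
        hkg=hkg,
        compounds=compounds,
        doses={cpd: tuple(float(d) for d in doses) for cpd in compounds},
        dr_params=dr,
        baseline=baseline,
        bg_mean=bg_mean,
        bg_sd=bg_sd,
        noise_sd=noise_sd,
        seed=seed,
    )
    for key, val in overrides.items():
        if not hasattr(truth, key):
            raise TypeError(f"unknown truth field {key!r}")
        setattr(truth, key, val)
    return truth


def simulate_beads(n_beads: int, mfi_center: float, dispersion: float, seed: int = 0) -> np.ndarray:
    """Log-normal bead-level fluorescence around ``mfi_center``.

    The median converges to the center as the bead count grows; dispersion 0
    gives identical beads (zero subsampling deviation).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    return mfi_center * np.exp(dispersion * rng.standard_normal(n_beads))


def simulate_deviation_curve(
    n_star: float,
    sizes=(10, 20, 30, 40, 50),
    slope: float = 0.4,
    plateau: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-|%dev| curve with a planted elbow at ``n_star``.

    Hockey-stick shape: |%dev| falls linearly with subsample size until
    ``n_star`` and is flat after, plus Gaussian noise on the per-size means —
    the idealized shape the breakpoint fit assumes, with the elbow location
    known exactly.
    """
    rng = np.random.default_rng(seed)
    n = np.asarray(sizes, dtype=float)
    y = plateau + slope * np.maximum(n_star - n, 0.0) + rng.normal(0.0, noise_sd, len(n))
    return n, y
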