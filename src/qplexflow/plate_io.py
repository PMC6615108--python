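"""Reading, merging and writing plate files.

Input files
-----------
* A template workbook (XLSX) with a sheet ``Plate`` (cell A1 = plate title,
  a header row ``Well, Compound, Concentration, Cell_count, Timepoint,
  Cell_line`` and one row per annotated well), a sheet ``HKG`` listing the
  housekeeping-gene names in column A, and an optional sheet ``Rawdata``
  whose cell A1 names the raw data file.
* A raw table (CSV/TSV, delimiter auto-detected among comma/semicolon/tab)
  in long format with columns ``well, gene, mfi, bead_count`` — one row per
  well x analyte with the median fluorescence intensity (MFI) and the number
  of beads that produced it.

Well roles are inferred from the template: a row whose compound field is the
literal ``background`` (case-insensitive) is a background well (no RNA
sample, measures technical noise); an annotated row without a compound, or
with concentration 0/absent and no compound, is a negative control (vehicle);
anything else annotated is a sample. Wells present in the raw file but never
annotated are discarded before analysis.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_WELL_RE = re.compile(r"^([A-Ha-h])\s*0*([1-9]\d?)$")

ROLE_SAMPLE = "sample"
ROLE_NEGATIVE = "negative_control"
ROLE_BACKGROUND = "background"

ANNOTATION_COLUMNS = ["role", "compound", "concentration", "cell_count", "timepoint", "cell_line"]


def normalize_well_id(well: str) -> str:
    """Canonicalize a 96-well coordinate: ``"B7"`` and ``"B07"`` -> ``"B07"``."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValidationError(f"not a valid 96-well coordinate: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 12:
        raise ValidationError(f"column {col} outside 96-well plate in {well!r}")
    return f"{row}{col:02d}"


@dataclass
class DiscardRecord:
    well_id: str
    gene: str  # "*" means every analyte of the well
    reason: str


@dataclass
class PlateTemplate:
    """Parsed template workbook: per-well annotations plus HKG names."""

    title: str
    annotations: pd.DataFrame  # index: well_id; columns: ANNOTATION_COLUMNS
    hkg_names: list[str]
    raw_file: str | None = None
    constant_columns: list[str] = field(default_factory=list)


@dataclass
class RawPlate:
    """Raw instrument export pivoted to wells x genes matrices."""

    mfi: pd.DataFrame  # wells x genes, float
    bead_counts: pd.DataFrame  # wells x genes, int (missing counts -> 0)

    @property
    def genes(self) -> list[str]:
        return list(self.mfi.columns)

    @property
    def wells(self) -> list[str]:
        return list(self.mfi.index)


@dataclass
class AnnotatedPlate:
    """Template annotations joined to raw MFI / bead counts.

    ``mfi`` entries removed by QC are set to NaN and listed in ``discarded``;
    a discarded entry never re-enters downstream stages.
    """

    title: str
    annotations: pd.DataFrame
    mfi: pd.DataFrame
    bead_counts: pd.DataFrame
    hkg_names: list[str]
    discarded: list[DiscardRecord] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.mfi.columns)

    def wells_with_role(self, role: str) -> list[str]:
        return list(self.annotations.index[self.annotations["role"] == role])

    def copy(self) -> "AnnotatedPlate":
        return AnnotatedPlate(
            title=self.title,
            annotations=self.annotations.copy(),
            mfi=self.mfi.copy(),
            bead_counts=self.bead_counts.copy(),
            hkg_names=list(self.hkg_names),
            discarded=list(self.discarded),
        )


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip() == ""


def _infer_role(compound, concentration) -> str:
    if not _is_blank(compound) and str(compound).strip().lower() == ROLE_BACKGROUND:
        return ROLE_BACKGROUND
    no_compound = _is_blank(compound)
    zero_dose = _is_blank(concentration) or float(concentration) == 0.0
    if no_compound and zero_dose:
        return ROLE_NEGATIVE
    if no_compound:  # concentration without compound: still vehicle
        return ROLE_NEGATIVE
    return ROLE_SAMPLE


def read_template(path: str | Path) -> PlateTemplate:
    """Read the template workbook (sheets ``Plate`` and ``HKG``)."""
    import openpyxl

    path = Path(path)
    try:
        wb = openpyxl.load_workbook(path, data_only=True)
    except Exception as exc:
        raise FormatError(f"{path.name} is not a readable xlsx workbook: {exc}") from exc
    for sheet in ("Plate", "HKG"):
        if sheet not in wb.sheetnames:
            raise FormatError(f"template workbook {path.name} is missing sheet {sheet!r}")

    plate = wb["Plate"]
    title = plate.cell(row=1, column=1).value
    title = "" if title is None else str(title)

    header = [str(c.value).strip().lower() if c.value is not None else "" for c in plate[2]]
    expected = ["well", "compound", "concentration", "cell_count", "timepoint", "cell_line"]
    col_of = {}
    for name in expected:
        if name in header:
            col_of[name] = header.index(name)
    if "well" not in col_of:
        raise FormatError("Plate sheet must have a 'Well' header in row 2")

    rows = []
    for excel_row in plate.iter_rows(min_row=3, values_only=True):
        if excel_row is None or all(_is_blank(v) for v in excel_row):
            continue
        rec = {name: (excel_row[idx] if idx < len(excel_row) else None) for name, idx in col_of.items()}
        if _is_blank(rec.get("well")):
            continue
        well = normalize_well_id(rec["well"])
        annot = {k: rec.get(k) for k in expected[1:]}
        if all(_is_blank(v) for v in annot.values()):
            raise ValidationError(f"well {well}: row present but no variable annotated")
        role = _infer_role(annot["compound"], annot["concentration"])
        compound = None if role != ROLE_SAMPLE else str(annot["compound"]).strip()
        conc = 0.0 if _is_blank(annot["concentration"]) else float(annot["concentration"])
        if conc < 0:
            raise ValidationError(f"well {well}: negative concentration {conc}")
        cell_count = None if _is_blank(annot["cell_count"]) else int(annot["cell_count"])
        rows.append(
            {
                "well_id": well,
                "role": role,
                "compound": compound,
                "concentration": conc,
                "cell_count": cell_count,
                "timepoint": None if _is_blank(annot["timepoint"]) else annot["timepoint"],
                "cell_line": None if _is_blank(annot["cell_line"]) else str(annot["cell_line"]),
            }
        )
    if not rows:
        raise ValidationError("Plate sheet contains no annotated wells")
    annotations = pd.DataFrame(rows).set_index("well_id")
    if annotations.index.duplicated().any():
        dups = sorted(set(annotations.index[annotations.index.duplicated()]))
        raise ValidationError(f"duplicate well annotations: {dups}")

    hkg_names = [
        str(row[0]).strip()
        for row in wb["HKG"].iter_rows(min_col=1, max_col=1, values_only=True)
        if row and not _is_blank(row[0])
    ]
    if not hkg_names:
        raise ValidationError("HKG sheet column A lists no housekeeping genes")

    raw_file = None
    if "Rawdata" in wb.sheetnames:
        cell = wb["Rawdata"].cell(row=1, column=1).value
        raw_file = None if _is_blank(cell) else str(cell).strip()

    constant = [c for c in ("cell_count", "timepoint", "cell_line") if annotations[c].isna().all()]
    return PlateTemplate(
        title=title,
        annotations=annotations.sort_index(),
        hkg_names=hkg_names,
        raw_file=raw_file,
        constant_columns=constant,
    )


def read_raw(path: str | Path) -> RawPlate:
    """Read a long-format raw table (well, gene, mfi, bead_count)."""
    path = Path(path)
    text = path.read_text()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",;\t")
        sep = dialect.delimiter
    except (csv.Error, IndexError):
        sep = ","
    df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"well", "gene", "mfi"}
    if not required.issubset(df.columns):
        raise FormatError(f"raw file {path.name} lacks columns {sorted(required - set(df.columns))}")
    df["well"] = df["well"].map(normalize_well_id)
    df["gene"] = df["gene"].astype(str).str.strip()
    dup = df.duplicated(subset=["well", "gene"])
    if dup.any():
        pairs = df.loc[dup, ["well", "gene"]].values.tolist()[:5]
        raise ValidationError(f"duplicated (well, gene) rows in raw file, e.g. {pairs}")
    mfi_num = pd.to_numeric(df["mfi"], errors="coerce")
    if mfi_num.isna().any():
        bad = df.loc[mfi_num.isna(), ["well", "gene", "mfi"]].values.tolist()[:5]
        raise ValidationError(f"non-numeric MFI values, e.g. {bad}")
    if (mfi_num < 0).any():
        raise ValidationError("negative MFI values in raw file")
    df["mfi"] = mfi_num
    if "bead_count" in df.columns:
        df["bead_count"] = pd.to_numeric(df["bead_count"], errors="coerce").fillna(0).astype(int)
    else:
        df["bead_count"] = 0
    mfi = df.pivot(index="well", columns="gene", values="mfi").sort_index()
    beads = (
        df.pivot(index="well", columns="gene", values="bead_count")
        .reindex(index=mfi.index, columns=mfi.columns)
        .fillna(0)
        .astype(int)
    )
    mfi.index.name = beads.index.name = "well_id"
    mfi.columns.name = beads.columns.name = "gene"
    # a (well, gene) pair absent from the file: MFI 0 / count 0, removed by the bead filter
    return RawPlate(mfi=mfi.fillna(0.0), bead_counts=beads)


def merge(template: PlateTemplate, raw: RawPlate) -> AnnotatedPlate:
    """Join template annotations to the raw matrices; discard unannotated wells."""
    annotated = template.annotations.index
    missing_hkg = [h for h in template.hkg_names if h not in raw.genes]
    if missing_hkg:
        raise ValidationError(f"HKG not present in raw data: {missing_hkg}")
    missing = sorted(set(annotated) - set(raw.wells))
    if missing:
        raise ValidationError(f"annotated wells absent from raw data: {missing}")
    discarded = [
        DiscardRecord(w, "*", "unannotated") for w in raw.wells if w not in set(annotated)
    ]
    keep = [w for w in raw.wells if w in set(annotated)]
    return AnnotatedPlate(
        title=template.title,
        annotations=template.annotations.loc[sorted(keep)],
        mfi=raw.mfi.loc[sorted(keep)].copy(),
        bead_counts=raw.bead_counts.loc[sorted(keep)].copy(),
        hkg_names=list(template.hkg_names),
        discarded=discarded,
    )


def results_table(fits, flags=None) -> pd.DataFrame:
    """One row per gene x compound with potency estimates and QC markers."""
    from .cytotox import annotate_fits

    if flags:
        fits = annotate_fits(fits, flags)
    rows = []
    for f in fits:
        marker = "~" if (f.ac50_abs is not None and f.uncertain) else ""
        rows.append(
            {
                "gene": f.gene,
                "compound": f.compound,
                "model": f.kind,
                "ac50_abs": f.ac50_abs,
                "log10_ac50": f.log10_ac50,
                "se_log10_ac50": f.se_log10_ac50,
                "ac50_marker": marker,
                "ac50_note": f.ac50_note or "",
                "hill_slope_b": f.params.get("b"),
                "se_b": f.se.get("b"),
                "max_effect_c": f.params.get("c"),
                "se_c": f.se.get("c"),
                "observed_max_fc": f.observed_max_fc,
                "fc_at_max_conc": f.fc_at_max,
                "direction": f.direction or "",
                "aic": f.aic,
                "cytotox_flag": bool(f.cytotox),
                "cytotox_doses": ";".join(str(d) for d in f.cytotox_doses),
            }
        )
    return pd.DataFrame(rows)


def qc_table(discarded: list[DiscardRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"well_id": d.well_id, "gene": d.gene, "reason": d.reason} for d in discarded],
        columns=["well_id", "gene", "reason"],
    )


def write_results(out_dir: str | Path, fits, flags=None, discarded=()) -> dict[str, Path]:
    """Write the result and QC tables as CSV; returns the paths written.

    Floats are serialized with shortest round-trip repr, so re-reading
    reproduces every numeric field exactly.
    """
    if not fits:
        raise ValidationError("no fits to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out_dir / "results.csv",
        "qc_discarded": out_dir / "qc_discarded.csv",
    }
    results_table(fits, flags).to_csv(paths["results"], index=False)
    qc_table(list(discarded)).to_csv(paths["qc_discarded"], index=False)
    return paths
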