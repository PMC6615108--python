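"""End-to-end orchestration of the plate-processing cascade.

Stage order is fixed: merge -> bead-count filter -> background stats and
correction -> LOQ well removal -> HKG stability filter -> normalization /
fold change -> cytotoxicity flags -> dose-response model selection -> AC50
extraction -> report emission. Every removal or flag lands in exactly one QC
table, and a run is fully determined by (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import background_loq, bead_qc, cytotox, dose_response, normalization, plate_io
from .background_loq import BackgroundStats, CorrectedMatrix
from .errors import QplexError
from .normalization import ExpressionMatrix, HKGStabilityReport
from .plate_io import AnnotatedPlate

logger = logging.getLogger("qplexflow")

MODE_OPTIMIZATION = "optimization"
MODE_SCREENING = "screening"


@dataclass
class RunConfig:
    """All tunable thresholds of the cascade, with the documented defaults."""

    bead_threshold: int = bead_qc.DEFAULT_BEAD_THRESHOLD  # 37 beads / gene / well
    loq_k: int = background_loq.DEFAULT_LOQ_K  # LOQ_10
    fc_range: tuple[float, float] = normalization.DEFAULT_FC_RANGE  # [0.8, 1.2]
    cytotox_threshold: float = cytotox.DEFAULT_CYTOTOX_REDUCTION  # 70% reduction
    fc_levels: tuple[float, float] = dose_response.DEFAULT_FC_LEVELS  # FC 0.5 / 1.5
    se_flag: float = dose_response.SE_UNCERTAIN_LOG10  # "~" above 0.3 log10 units
    min_bg_wells_warn: int = background_loq.MIN_BACKGROUND_WELLS_ADVISED  # 6
    min_neg_wells_warn: int = normalization.MIN_NEGATIVE_WELLS_ADVISED  # 6
    subsample_sizes: tuple[int, ...] = bead_qc.DEFAULT_SUBSAMPLE_SIZES
    subsample_reps: int = bead_qc.DEFAULT_SUBSAMPLE_REPS
    seed: int = 0
    mode: str = MODE_OPTIMIZATION  # screening: cytotox wells excluded from HKG stability

    def __post_init__(self):
        if self.bead_threshold < 1:
            raise ValueError("bead_threshold must be >= 1")
        if not 0 < self.cytotox_threshold < 1:
            raise ValueError("cytotox_threshold is a fraction in (0, 1)")
        if self.mode not in (MODE_OPTIMIZATION, MODE_SCREENING):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("fc_range", "fc_levels", "subsample_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("fc_range", "fc_levels", "subsample_sizes"):
            d[key] = list(d[key])
        return d


@dataclass
class RunResult:
    plate: AnnotatedPlate
    bead_report: bead_qc.BeadFilterReport
    stats: BackgroundStats
    corrected: CorrectedMatrix
    stability: HKGStabilityReport
    fc: ExpressionMatrix
    flags: list
    fits: list
    warnings: list[str] = field(default_factory=list)

    @property
    def results(self) -> pd.DataFrame:
        return plate_io.results_table(self.fits, self.flags)


def run_plate(plate: AnnotatedPlate, config: RunConfig | None = None) -> RunResult:
    """Run the full cascade on an in-memory annotated plate."""
    config = config or RunConfig()
    logger.info("stage bead_filter: threshold %d", config.bead_threshold)
    plate, bead_report = bead_qc.filter_by_bead_count(plate, config.bead_threshold)
    for w, g, n in bead_report.removed:
        logger.info("bead_filter: removed %s/%s (%d beads)", w, g, n)

    logger.info("stage background")
    stats = background_loq.background_stats(plate)
    corrected = background_loq.background_correct(plate, stats)
    corrected = background_loq.remove_wells_below_loq(corrected, plate.hkg_names, k=config.loq_k)
    for rec in corrected.removed_wells:
        logger.info("loq_removal: well %s (%s, %s)", rec.well_id, rec.hkg, rec.reason)
        plate.discarded.append(plate_io.DiscardRecord(rec.well_id, "*", f"loq:{rec.reason}"))

    exclude: tuple[str, ...] = ()
    if config.mode == MODE_SCREENING:
        # first-pass cytotox on the full corrected matrix, so that compound
        # toxicity does not masquerade as HKG instability
        pre_flags = cytotox.cytotox_flags(
            corrected, plate.annotations, plate.hkg_names, config.cytotox_threshold
        )
        flagged = {(f.compound, f.dose) for f in pre_flags}
        exclude = tuple(
            w
            for w in corrected.values.index
            if (plate.annotations.at[w, "compound"], plate.annotations.at[w, "concentration"])
            in flagged
        )

    logger.info("stage hkg_stability")
    stability = normalization.hkg_stability_filter(
        corrected, plate.annotations, plate.hkg_names, fc_range=config.fc_range,
        exclude_wells=exclude,
    )
    for h, it, ext in stability.removed:
        logger.info("hkg_stability: removed %s at iteration %d (FC %.3f)", h, it, ext)

    logger.info("stage normalization")
    fc = normalization.compute_fc(
        corrected, plate.annotations, stability.retained,
        min_negative_warn=config.min_neg_wells_warn,
    )

    logger.info("stage cytotox")
    flags = cytotox.cytotox_flags(
        corrected, plate.annotations, stability.retained, config.cytotox_threshold
    )
    for f in flags:
        logger.info("cytotox: %s @ %g (%s, dose_dependent=%s)",
                    f.compound, f.dose, ",".join(f.triggering_hkg), f.dose_dependent)

    logger.info("stage dose_response")
    fits = dose_response.analyze_dose_responses(
        fc.values, plate.annotations, hkg_names=plate.hkg_names,
        fc_range=config.fc_range, fc_levels=config.fc_levels,
    )
    fits = cytotox.annotate_fits(fits, flags)
    return RunResult(
        plate=plate,
        bead_report=bead_report,
        stats=stats,
        corrected=corrected,
        stability=stability,
        fc=fc,
        flags=flags,
        fits=fits,
    )


def run(
    template_path: str | Path,
    raw_path: str | Path | None,
    out_dir: str | Path,
    config: RunConfig | None = None,
    plots: bool = False,
) -> RunResult:
    """File-level entry point: read, process, and write the report directory.

    ``raw_path`` may be omitted when the template's Rawdata sheet names the
    raw file (resolved relative to the template).
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        template = plate_io.read_template(template_path)
        if raw_path is None:
            if not template.raw_file:
                raise QplexError("no raw file given and no Rawdata sheet in the template")
            raw_path = Path(template_path).parent / template.raw_file
        raw = plate_io.read_raw(raw_path)
        plate = plate_io.merge(template, raw)
        result = run_plate(plate, config)
    except QplexError:
        (out_dir / "INCOMPLETE").write_text("run aborted; see run.log\n")
        logger.exception("run aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    _write_reports(result, config, out_dir)
    if plots:
        _write_plots(result, out_dir)
    return result


def _write_reports(result: RunResult, config: RunConfig, out_dir: Path) -> None:
    plate_io.write_results(out_dir, result.fits, result.flags, result.plate.discarded)
    result.stats.table.to_csv(out_dir / "qc_background.csv")
    pd.DataFrame(
        [
            {"well_id": r.well_id, "hkg": r.hkg, "value": r.value, "reason": r.reason}
            for r in result.corrected.removed_wells
        ],
        columns=["well_id", "hkg", "value", "reason"],
    ).to_csv(out_dir / "qc_removed_wells.csv", index=False)
    pd.DataFrame(
        [{"hkg": h, "iteration": it, "fc_extremum": ext} for h, it, ext in result.stability.removed],
        columns=["hkg", "iteration", "fc_extremum"],
    ).to_csv(out_dir / "qc_hkg_stability.csv", index=False)
    result.stability.condition_summary.to_csv(out_dir / "qc_hkg_fc_summary.csv", index=False)
    cytotox.flags_table(result.flags).to_csv(out_dir / "qc_cytotox.csv", index=False)
    summary = {
        "title": result.plate.title,
        "config": config.to_dict(),
        "n_wells_annotated": int(len(result.plate.annotations)),
        "n_entries_removed_low_beads": len(result.bead_report.removed),
        "n_wells_removed_loq": len(result.corrected.removed_wells),
        "hkg_retained": result.stability.retained,
        "hkg_removed": [h for h, _, _ in result.stability.removed],
        "n_cytotox_conditions": len(result.flags),
        "n_fits": len(result.fits),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def _write_plots(result: RunResult, out_dir: Path) -> None:
    """Static QC figures: background levels with LOQ lines, HKG FC by dose."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    t = result.stats.table
    ax.errorbar(range(len(t)), t["bg_mean"], yerr=t["bg_sd"], fmt="o", label="background")
    for k, color in ((3, "tab:blue"), (5, "tab:red"), (10, "tab:green")):
        ax.plot(range(len(t)), t[f"loq_{k}"], color=color, lw=1, label=f"LOQ_{k}")
    ax.set_xticks(range(len(t)))
    ax.set_xticklabels(t.index, rotation=90, fontsize=6)
    ax.set_ylabel("MFI")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "qc_background.png", dpi=120)
    plt.close(fig)
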