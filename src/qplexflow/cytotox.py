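"""Cytotoxicity flags from background-corrected housekeeping-gene signals.

A compound that kills cells suppresses every transcript, housekeeping genes
included — and because HKG normalization divides that suppression away, the
fold-change view can look deceptively normal. The flag therefore works on
the background-corrected (pre-normalization) HKG signal: a compound x dose
condition is cytotoxic when, for at least one HKG, its corrected signal
drops below 30% of the mean corrected negative-control signal (a > 70%
reduction), and dose dependence is recorded as the flagged doses forming an
upper set of the compound's dose ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .background_loq import CorrectedMatrix
from .errors import StageError, ValidationError
from .plate_io import ROLE_NEGATIVE, ROLE_SAMPLE

DEFAULT_CYTOTOX_REDUCTION = 0.70


@dataclass
class CytotoxFlag:
    compound: str
    dose: float
    triggering_hkg: list[str]
    neg_mean: dict[str, float]
    reduction: float  # fraction of the negative-control mean lost (worst HKG)
    dose_dependent: bool


def cytotox_flags(
    corrected: CorrectedMatrix | pd.DataFrame,
    annotations: pd.DataFrame,
    hkg_names: list[str],
    threshold: float = DEFAULT_CYTOTOX_REDUCTION,
) -> list[CytotoxFlag]:
    """Flag compound x dose conditions whose HKG signal collapses.

    Per HKG h the cutoff is ``(1 - threshold) * mean(corrected negative
    controls)``; the condition value is the median over its replicate wells,
    and the flag fires on a strict drop below the cutoff for >= 1 HKG.
    ``dose_dependent`` is True when every higher dose of the same compound is
    flagged as well; non-dose-dependent drops are still listed so users see
    them.
    """
    if not hkg_names:
        raise ValidationError("hkg_names must be nonempty")
    values = corrected.values if isinstance(corrected, CorrectedMatrix) else corrected
    neg = [w for w in values.index if annotations.at[w, "role"] == ROLE_NEGATIVE]
    if not neg:
        raise StageError("no negative-control wells; cytotoxicity cutoff undefined")
    neg_mean = values.loc[neg, list(hkg_names)].mean(axis=0)
    cutoff = (1.0 - threshold) * neg_mean

    sample = [w for w in values.index if annotations.at[w, "role"] == ROLE_SAMPLE]
    if not sample:
        return []
    cond = values.loc[sample, list(hkg_names)].groupby(
        [annotations.loc[sample, "compound"], annotations.loc[sample, "concentration"]]
    ).median()

    flagged: dict[str, list[tuple[float, list[str], float]]] = {}
    for (cpd, dose), row in cond.iterrows():
        trig = [h for h in hkg_names if row[h] < cutoff[h]]
        if trig:
            red = max(1.0 - row[h] / neg_mean[h] if neg_mean[h] > 0 else 1.0 for h in trig)
            flagged.setdefault(cpd, []).append((float(dose), trig, float(red)))

    ladders = {
        cpd: sorted(annotations.loc[sample].query("compound == @cpd")["concentration"].unique())
        for cpd in {c for c, _ in cond.index}
    }
    flags = []
    for cpd in sorted(flagged):
        flagged_doses = {d for d, _, _ in flagged[cpd]}
        for dose, trig, red in sorted(flagged[cpd]):
            higher = [d for d in ladders[cpd] if d > dose]
            flags.append(
                CytotoxFlag(
                    compound=cpd,
                    dose=dose,
                    triggering_hkg=trig,
                    neg_mean={h: float(neg_mean[h]) for h in hkg_names},
                    reduction=red,
                    dose_dependent=all(d in flagged_doses for d in higher),
                )
            )
    return flags


def flags_table(flags: list[CytotoxFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": f.compound,
                "dose": f.dose,
                "triggering_hkg": ";".join(f.triggering_hkg),
                "reduction": f.reduction,
                "dose_dependent": f.dose_dependent,
            }
            for f in flags
        ],
        columns=["compound", "dose", "triggering_hkg", "reduction", "dose_dependent"],
    )


def annotate_fits(fits, flags: list[CytotoxFlag]):
    """Attach the cytotox marker and flagged doses to every fit of a flagged compound."""
    by_compound: dict[str, list[float]] = {}
    for f in flags:
        by_compound.setdefault(f.compound, []).append(f.dose)
    out = []
    for fit in fits:
        if fit.compound in by_compound:
            fit.cytotox = True
            fit.cytotox_doses = sorted(by_compound[fit.compound])
        out.append(fit)
    return out
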