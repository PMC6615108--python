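"""Geometric-mean normalization, fold change, iterative HKG stability filter."""

import numpy as np
import pandas as pd
import pytest

from qplexflow import (
    compute_fc,
    fold_change,
    geometric_mean_hkg,
    hkg_stability_filter,
    relative_expression,
)
from qplexflow.errors import StabilityError, StageError, ValidationError
from tests.conftest import build_plate

NEG = ("negative_control", None, 0.0)


def _frame(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """rows: well -> {gene: corrected value}."""
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


def _annotations(roles: dict[str, tuple]) -> pd.DataFrame:
    ann = pd.DataFrame.from_dict(
        {w: {"role": r, "compound": c, "concentration": d} for w, (r, c, d) in roles.items()},
        orient="index",
    )
    ann.index.name = "well_id"
    return ann


def test_geometric_mean_hand_values():
    vals = _frame({"A01": {"HKG1": 4.0, "HKG2": 9.0, "G1": 7.0},
                   "A02": {"HKG1": 1.0, "HKG2": 1.0, "G1": 3.0}})
    gm = geometric_mean_hkg(vals, ["HKG1", "HKG2"])
    assert gm["A01"] == pytest.approx(6.0)  # sqrt(4*9)
    assert gm["A02"] == pytest.approx(1.0)
    gm3 = geometric_mean_hkg(
        _frame({"A01": {"HKG1": 1.0, "HKG2": 1.0, "HKG3": 8.0}}), ["HKG1", "HKG2", "HKG3"]
    )
    assert gm3["A01"] == pytest.approx(2.0)  # cbrt(8)


def test_geometric_mean_zero_hkg_warns_and_relative_refuses():
    vals = _frame({"A01": {"HKG1": 0.0, "HKG2": 9.0, "G1": 7.0}})
    with pytest.warns(UserWarning, match="geometric mean 0"):
        gm = geometric_mean_hkg(vals, ["HKG1", "HKG2"])
    assert gm["A01"] == 0.0
    with pytest.raises(StageError):
        relative_expression(vals, gm)


def test_geometric_mean_requires_hkg():
    with pytest.raises(ValidationError):
        geometric_mean_hkg(_frame({"A01": {"G1": 1.0}}), [])


def test_relative_times_geomean_recovers_corrected():
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(rng.uniform(10, 500, (8, 4)),
                        index=[f"A{i+1:02d}" for i in range(8)],
                        columns=["HKG1", "HKG2", "G1", "G2"])
    gm = geometric_mean_hkg(vals, ["HKG1", "HKG2"])
    rel = relative_expression(vals, gm)
    assert np.allclose(rel.values.mul(gm, axis=0), vals)


def test_fold_change_hand_example_and_negative_median_is_one():
    vals = _frame({
        "A01": {"HKG1": 100.0, "G1": 50.0},   # negative controls
        "A02": {"HKG1": 100.0, "G1": 60.0},
        "A03": {"HKG1": 100.0, "G1": 70.0},
        "B01": {"HKG1": 200.0, "G1": 240.0},  # sample, scaled 2x overall
    })
    ann = _annotations({"A01": NEG, "A02": NEG, "A03": NEG, "B01": ("sample", "c", 1.0)})
    with pytest.warns(UserWarning, match="negative-control wells"):
        fc = compute_fc(vals, ann, ["HKG1"])
    # neg relative G1: 0.5, 0.6, 0.7 -> median 0.6; sample relative 1.2 -> FC 2
    assert fc.values.loc["B01", "G1"] == pytest.approx(2.0)
    assert fc.values.loc["A02", "G1"] == pytest.approx(1.0)
    # per-gene median over negative controls is exactly 1 by construction
    neg_fc = fc.values.loc[["A01", "A02", "A03"]]
    assert np.allclose(neg_fc.median(axis=0), 1.0)


def test_fold_change_scale_invariance():
    """Multiplying any well by a constant leaves every FC unchanged."""
    rng = np.random.default_rng(5)
    wells = [f"A{i+1:02d}" for i in range(6)] + [f"B{i+1:02d}" for i in range(6)]
    vals = pd.DataFrame(rng.uniform(50, 400, (12, 4)), index=wells,
                        columns=["HKG1", "HKG2", "G1", "G2"])
    roles = {w: NEG for w in wells[:6]}
    roles.update({w: ("sample", "c", float(i)) for i, w in enumerate(wells[6:], 1)})
    ann = _annotations(roles)
    fc = compute_fc(vals, ann, ["HKG1", "HKG2"])
    scales = pd.Series(rng.uniform(0.2, 5.0, 12), index=wells)
    fc_scaled = compute_fc(vals.mul(scales, axis=0), ann, ["HKG1", "HKG2"])
    pd.testing.assert_frame_equal(fc.values, fc_scaled.values)


def test_fold_change_drops_gene_with_zero_negative_median():
    vals = _frame({f"A{i+1:02d}": {"HKG1": 100.0, "G1": 0.0, "G2": 50.0} for i in range(6)})
    vals.loc["B01"] = [100.0, 80.0, 60.0]
    ann = _annotations(dict({f"A{i+1:02d}": NEG for i in range(6)},
                            B01=("sample", "c", 1.0)))
    with pytest.warns(UserWarning, match="G1"):
        fc = compute_fc(vals, ann, ["HKG1"])
    assert fc.missing_genes == ["G1"]
    assert "G1" not in fc.values.columns and "G2" in fc.values.columns


def test_fold_change_without_negative_controls_errors():
    vals = _frame({"B01": {"HKG1": 100.0, "G1": 50.0}})
    ann = _annotations({"B01": ("sample", "c", 1.0)})
    with pytest.raises(StageError):
        compute_fc(vals, ann, ["HKG1"])


def _three_hkg_case():
    """Worked construction: HKG A drifts in sample wells, B and C do not.

    Negative controls: all HKG at 100. Sample wells: A at 260, B and C at 100.
    With all three in the geometric mean, sample FC are
    A: (260/s)/(100/100) where s = cbrt(260*100*100) ~ 137.5 -> ~1.891
    B, C: 100/s * 1 -> ~0.727 — so a batch rule would discard all three,
    while the iterative rule removes only A and then finds B, C stable.
    """
    wells_neg = [f"A{i+1:02d}" for i in range(6)]
    wells_smp = [f"B{i+1:02d}" for i in range(4)]
    rows = {w: {"HKG_A": 100.0, "HKG_B": 100.0, "HKG_C": 100.0, "G1": 100.0}
            for w in wells_neg}
    rows.update({w: {"HKG_A": 260.0, "HKG_B": 100.0, "HKG_C": 100.0, "G1": 100.0}
                 for w in wells_smp})
    roles = {w: NEG for w in wells_neg}
    roles.update({w: ("sample", "c", float(i)) for i, w in enumerate(wells_smp, 1)})
    return _frame(rows), _annotations(roles)


def test_stability_filter_iterative_beats_batch_removal():
    vals, ann = _three_hkg_case()
    report = hkg_stability_filter(vals, ann, ["HKG_A", "HKG_B", "HKG_C"])
    assert report.retained == ["HKG_B", "HKG_C"]
    assert [h for h, _, _ in report.removed] == ["HKG_A"]
    # the offending extremum recorded for A is its inflated FC
    _, iteration, extremum = report.removed[0]
    assert iteration == 1
    s = (260.0 * 100.0 * 100.0) ** (1 / 3)
    assert extremum == pytest.approx(260.0 / s, rel=1e-12)


def test_stability_filter_all_stable_is_identity():
    rng = np.random.default_rng(11)
    wells = [f"A{i+1:02d}" for i in range(6)] + [f"B{i+1:02d}" for i in range(6)]
    base = pd.Series(rng.uniform(80, 300, 3), index=["HKG1", "HKG2", "G1"])
    vals = pd.DataFrame(
        {g: base[g] * np.exp(rng.normal(0, 0.01, 12)) for g in base.index}, index=wells
    )
    roles = {w: NEG for w in wells[:6]}
    roles.update({w: ("sample", "c", float(i)) for i, w in enumerate(wells[6:], 1)})
    report = hkg_stability_filter(vals, _annotations(roles), ["HKG1", "HKG2"])
    assert report.retained == ["HKG1", "HKG2"]
    assert report.removed == []


def test_stability_filter_boundary_values_are_stable():
    """FC exactly at 0.8 or 1.2 does not trigger removal (strict inequality)."""
    wells_neg = [f"A{i+1:02d}" for i in range(6)]
    rows = {w: {"HKG1": 100.0, "HKG2": 100.0, "G1": 100.0} for w in wells_neg}
    # two HKG: FC_1 = sqrt(f), so f = 1.44 puts HKG1 exactly at FC 1.2
    rows["B01"] = {"HKG1": 144.0, "HKG2": 100.0, "G1": 100.0}
    roles = dict({w: NEG for w in wells_neg}, B01=("sample", "c", 1.0))
    report = hkg_stability_filter(_frame(rows), _annotations(roles), ["HKG1", "HKG2"])
    assert report.retained == ["HKG1", "HKG2"]


def test_stability_filter_single_hkg_has_identity_fc():
    """Normalizing an HKG by itself gives FC exactly 1, so the filter always
    terminates with at least one retained HKG even for wildly drifting data."""
    wells_neg = [f"A{i+1:02d}" for i in range(6)]
    rows = {w: {"HKG1": 100.0, "G1": 100.0} for w in wells_neg}
    rows["B01"] = {"HKG1": 700.0, "G1": 400.0}
    vals = _frame(rows)
    roles = dict({w: NEG for w in wells_neg}, B01=("sample", "c", 1.0))
    report = hkg_stability_filter(vals, _annotations(roles), ["HKG1"])
    assert report.retained == ["HKG1"]

    # two HKG drifting in opposite directions: the worse one goes first,
    # the survivor is then stable by the identity above
    rows = {w: {"HKG1": 100.0, "HKG2": 100.0, "G1": 100.0} for w in wells_neg}
    rows["B01"] = {"HKG1": 300.0, "HKG2": 50.0, "G1": 100.0}
    roles = dict({w: NEG for w in wells_neg}, B01=("sample", "c", 1.0))
    report = hkg_stability_filter(_frame(rows), _annotations(roles), ["HKG1", "HKG2"])
    assert report.retained == ["HKG2"]  # HKG1's excursion is larger
    assert [h for h, _, _ in report.removed] == ["HKG1"]


def test_stability_filter_exclude_wells_masks_offender():
    """The drifting well is ignored when listed in exclude_wells."""
    vals, ann = _three_hkg_case()
    excl = tuple(w for w in vals.index if w.startswith("B"))
    report = hkg_stability_filter(vals, ann, ["HKG_A", "HKG_B", "HKG_C"],
                                  exclude_wells=excl)
    assert report.retained == ["HKG_A", "HKG_B", "HKG_C"]


def test_stability_filter_terminates_within_hkg_count():
    vals, ann = _three_hkg_case()
    report = hkg_stability_filter(vals, ann, ["HKG_A", "HKG_B", "HKG_C"])
    assert len(report.removed) <= 2  # at most |hkg| - 1 removals


def test_condition_summary_matches_manual_grouping():
    vals, ann = _three_hkg_case()
    report = hkg_stability_filter(vals, ann, ["HKG_A", "HKG_B", "HKG_C"])
    summary = report.condition_summary
    assert set(summary["hkg"]) == {"HKG_B", "HKG_C"}
    # after removing A, geometric mean of B and C is 100 in sample wells -> FC 1
    assert np.allclose(summary["fc_mean"], 1.0)
    assert len(summary) == 2 * 4  # 2 HKG x 4 sample conditions
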