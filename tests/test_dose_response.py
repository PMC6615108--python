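"""3PL fitting, AIC model selection, absolute AC50 and its delta-method SE."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from qplexflow import (
    absolute_ac50,
    analyze_dose_responses,
    fit_3pl,
    fit_constant,
    log_logistic,
    select_model,
)
from qplexflow.dose_response import DoseSeries, _gaussian_aic, _weights
from qplexflow.errors import FitError, ValidationError

DOSES = 0.1 * 10 ** (np.arange(6) / 2)  # half-log ladder 0.1 .. ~31.6


def _series(b, c, e, doses=DOSES, noise=None, gene="G", compound="C"):
    y = log_logistic(doses, b, c, e)
    if noise is not None:
        y = y * np.exp(noise)
    return DoseSeries(gene=gene, compound=compound, x=np.asarray(doses, float), y=y)


def test_log_logistic_zero_dose_is_exactly_one():
    assert log_logistic(np.array([0.0]), 2.0, 0.1, 1.0)[0] == 1.0
    # limits: far below e -> d, far above -> c
    assert log_logistic(np.array([1e-12]), 1.0, 0.2, 0.0)[0] == pytest.approx(1.0, abs=1e-9)
    assert log_logistic(np.array([1e12]), 1.0, 0.2, 0.0)[0] == pytest.approx(0.2, abs=1e-9)


def test_log_logistic_monotone_between_asymptotes():
    x = np.logspace(-4, 4, 200)
    y = log_logistic(x, 1.3, 0.2, 0.5)
    assert (np.diff(y) < 0).all()
    assert ((y > 0.2) & (y < 1.0)).all()


def test_series_validation():
    with pytest.raises(ValidationError):
        DoseSeries("g", "c", [1.0, 2.0], [1.0])
    with pytest.raises(ValidationError):
        DoseSeries("g", "c", [-1.0], [1.0])
    with pytest.raises(ValidationError):
        DoseSeries("g", "c", [1.0], [np.nan])


def test_constant_fit_hand_computed_aic():
    """y = {1.0, 1.1, 0.9, 1.05}: mean 1.0125, RSS = 0.021875, k = 2."""
    s = DoseSeries("g", "c", [0.1, 1.0, 10.0, 100.0], [1.0, 1.1, 0.9, 1.05])
    fit = fit_constant(s)
    assert fit.params["level"] == pytest.approx(1.0125)
    rss = sum((v - 1.0125) ** 2 for v in [1.0, 1.1, 0.9, 1.05])
    assert rss == pytest.approx(0.021875)
    expected = 4 * (math.log(2 * math.pi * rss / 4) + 1) + 4
    assert fit.aic == pytest.approx(expected, rel=1e-12)
    assert fit.ac50_abs is None


def test_weights_are_inverse_squared_fc_with_zero_handling():
    s = DoseSeries("g", "c", [1.0, 10.0, 100.0], [2.0, 0.5, 0.0])
    with pytest.warns(UserWarning, match="max finite weight"):
        w = _weights(s)
    assert w[0] == 0.25 and w[1] == 4.0 and w[2] == 4.0
    with pytest.raises(FitError):
        _weights(DoseSeries("g", "c", [1.0, 2.0], [0.0, 0.0]))


@pytest.mark.parametrize("weighted", [False, True])
@pytest.mark.parametrize(
    "truth", [(1.0, 0.2, math.log(3.0)), (2.0, 0.05, math.log(0.5)), (0.8, 2.5, math.log(5.0))]
)
def test_3pl_recovers_noise_free_parameters(truth, weighted):
    b, c, e = truth
    fit = fit_3pl(_series(b, c, e), weighted=weighted)
    assert fit.converged
    assert fit.params["b"] == pytest.approx(b, abs=1e-4)
    assert fit.params["c"] == pytest.approx(c, abs=1e-4)
    assert fit.params["e_tilde"] == pytest.approx(e, abs=1e-4)


def test_3pl_needs_two_distinct_nonzero_doses():
    with pytest.raises(FitError):
        fit_3pl(DoseSeries("g", "c", [0.0, 1.0, 1.0], [1.0, 0.5, 0.55]))


def test_3pl_zero_dose_anchors_at_one():
    doses = np.concatenate([[0.0], DOSES])
    fit = fit_3pl(_series(1.0, 0.2, math.log(1.0), doses=doses))
    assert float(np.asarray(fit.predict([0.0]))[0]) == 1.0


def test_absolute_ac50_closed_form_examples():
    # decreasing, b=1, c=0, e=log 10: 0.5 = 1/(1+exp(log x - log 10)) -> x = 10
    fit = fit_3pl(_series(1.0, 1e-9, math.log(10.0)))
    ac50, se = absolute_ac50(fit)
    assert ac50 == pytest.approx(10.0, rel=1e-4)
    # increasing, b=1, c=2, e=log 10: 1.5 = 2 - 1/(1+exp(...)) -> x = 10
    fit = fit_3pl(_series(1.0, 2.0, math.log(10.0)))
    ac50, _ = absolute_ac50(fit)
    assert ac50 == pytest.approx(10.0, rel=1e-4)
    assert fit.direction == "increasing"


def test_absolute_ac50_matches_bisection():
    """Closed form equals a numeric root of f(x) = 0.5 on the fitted curve."""
    fit = fit_3pl(_series(2.0, 0.2, math.log(5.0)))
    ac50, _ = absolute_ac50(fit)
    b, c, e = fit.params["b"], fit.params["c"], fit.params["e_tilde"]
    root = brentq(lambda x: log_logistic(np.array([x]), b, c, e)[0] - 0.5, 1e-8, 1e8)
    assert ac50 == pytest.approx(root, rel=1e-10)


def test_absolute_ac50_level_not_reached():
    # decreasing but plateau c = 0.7 > 0.5: curve never crosses FC 0.5
    fit = fit_3pl(_series(1.5, 0.7, math.log(2.0)))
    ac50, se = absolute_ac50(fit)
    assert ac50 is None and se is None
    assert fit.ac50_note == "level not reached"
    # weak induction c = 1.3 < 1.5 likewise
    fit = fit_3pl(_series(1.5, 1.3, math.log(2.0)))
    assert absolute_ac50(fit) == (None, None)


def test_absolute_ac50_rejects_constant_fit():
    s = DoseSeries("g", "c", [1.0, 10.0], [1.0, 1.0])
    with pytest.raises(FitError):
        absolute_ac50(fit_constant(s))


def test_delta_method_se_matches_finite_differences():
    """SE(log10 AC50) from the gradient formula equals a numeric differentiation
    of log10 AC50(b, c, e) against the same covariance."""
    rng = np.random.default_rng(17)
    s = _series(1.2, 0.15, math.log(2.0), noise=rng.normal(0, 0.05, len(DOSES)))
    fit = fit_3pl(s, weighted=True)
    ac50, se = absolute_ac50(fit)
    assert se is not None
    b, c, e = fit.params["b"], fit.params["c"], fit.params["e_tilde"]

    def log10_ac50(theta):
        bb, cc, ee = theta
        return (ee + math.log((1 - 0.5) / (0.5 - cc)) / bb) / math.log(10)

    h = 1e-7
    theta = np.array([b, c, e])
    grad = np.array([
        (log10_ac50(theta + h * np.eye(3)[i]) - log10_ac50(theta - h * np.eye(3)[i])) / (2 * h)
        for i in range(3)
    ])
    var = float(grad @ fit.cov @ grad)
    assert se == pytest.approx(math.sqrt(var), rel=1e-5)


def test_uncertainty_flag_threshold():
    rng = np.random.default_rng(23)
    s = _series(1.0, 0.2, math.log(1.0), noise=rng.normal(0, 0.03, len(DOSES)))
    fit = fit_3pl(s, weighted=True)
    absolute_ac50(fit)
    assert fit.se_log10_ac50 < 0.3 and not fit.uncertain
    # covariance unavailable -> uncertain regardless
    fit.cov = None
    fit.se_log10_ac50 = None
    absolute_ac50(fit)
    assert fit.uncertain


def test_select_model_all_in_range_returns_constant_without_fitting():
    s = DoseSeries("g", "c", DOSES, np.full(len(DOSES), 1.05))
    fit = select_model(s)
    assert fit.kind == "constant"
    assert "uninformative" in fit.ac50_note
    assert fit.fc_at_max == pytest.approx(1.05)


def test_select_model_prefers_sigmoid_on_strong_signal():
    fit = select_model(_series(1.2, 0.2, math.log(1.0)))
    assert fit.kind in ("pl3", "pl3_weighted")
    assert fit.ac50_abs is not None
    assert fit.direction == "decreasing"


def test_select_model_aic_tie_breaks_to_simpler(monkeypatch):
    import qplexflow.dose_response as dr

    monkeypatch.setattr(dr, "_gaussian_aic", lambda *a, **k: 0.0)
    s = DoseSeries("g", "c", DOSES, log_logistic(DOSES, 1.0, 0.2, 0.0))
    fit = dr.select_model(s)
    assert fit.kind == "constant"


def test_select_model_weighted_wins_under_heteroscedastic_noise():
    """Multiplicative noise (variance growing with FC^2) is the regime the
    1/FC^2 weights encode; AIC should prefer the weighted fit most of the time."""
    rng = np.random.default_rng(31)
    kinds = {"constant": 0, "pl3": 0, "pl3_weighted": 0}
    for _ in range(60):
        s = _series(1.2, 2.8, math.log(1.0), noise=rng.normal(0, 0.08, len(DOSES)))
        kinds[select_model(s).kind] += 1
    assert kinds["pl3_weighted"] > kinds["pl3"]
    assert kinds["pl3_weighted"] > kinds["constant"]


def test_absolute_ac50_robust_to_truncated_dose_range():
    """Dropping the top two doses barely moves the absolute AC50 while the
    relative AC50 exp(e) shifts much more (the rationale for reporting it)."""
    b, c, e = 1.0, 0.05, math.log(8.0)
    rng = np.random.default_rng(41)
    abs_shifts, rel_shifts = [], []
    for _ in range(20):
        noise = rng.normal(0, 0.05, len(DOSES))
        full = fit_3pl(_series(b, c, e, noise=noise), weighted=True)
        absolute_ac50(full)
        trunc = fit_3pl(_series(b, c, e, doses=DOSES[:-2], noise=noise[:-2]), weighted=True)
        absolute_ac50(trunc)
        if full.ac50_abs is None or trunc.ac50_abs is None:
            continue  # truncated fit can legitimately end 'level not reached'
        abs_shifts.append(abs(math.log10(trunc.ac50_abs) - math.log10(full.ac50_abs)))
        rel_shifts.append(abs(trunc.params["e_tilde"] - full.params["e_tilde"]) / math.log(10))
    assert len(abs_shifts) >= 10  # most draws keep the AC50 in reach
    assert np.median(abs_shifts) < np.median(rel_shifts)
    assert np.mean(abs_shifts) < np.mean(rel_shifts)


def test_analyze_dose_responses_skips_hkg_columns():
    import pandas as pd

    wells = [f"B{i+1:02d}" for i in range(6)]
    ann = pd.DataFrame(
        {"role": "sample", "compound": "cpd", "concentration": DOSES}, index=wells
    )
    fc = pd.DataFrame(
        {"HKG1": 1.0, "G1": log_logistic(DOSES, 1.0, 0.2, 0.0)}, index=wells
    )
    fits = analyze_dose_responses(fc, ann, hkg_names=["HKG1"])
    assert [f.gene for f in fits] == ["G1"]


def test_gaussian_aic_reduces_to_unweighted_form():
    rss, n = 0.05, 8
    assert _gaussian_aic(rss, n, k=2) == pytest.approx(
        n * (math.log(2 * math.pi * rss / n) + 1) + 4
    )
    # uniform weights w = 2 shift the AIC by -n log 2 with rss_w = 2 rss
    assert _gaussian_aic(2 * rss, n, k=2, log_w_sum=n * math.log(2)) == pytest.approx(
        _gaussian_aic(rss, n, k=2) - 0.0, abs=1e-9
    )
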