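"""Dose-response modelling of fold changes and absolute AC50 extraction.

The mean fold change (FC) as a function of dose x is modelled with a
three-parameter log-logistic (Hill) curve

    E(y) = f(x; b, c, e) = c + (d - c) / (1 + exp(b * (log x - e))),

with the zero-dose plateau fixed at d = 1 (the negative-control FC), Hill
slope b > 0, second asymptote c > 0, and e = log of the curve's inflection
dose (the relative AC50). Per gene x compound, model selection follows a
fixed scheme: if every FC lies inside [0.8, 1.2] the response is
uninformative and an intercept-only (constant) fit is used; otherwise a
constant fit, a 3PL fit and a 1/FC^2-weighted 3PL fit (down-weighting high
FC to tame variance heterogeneity) compete on AIC.

Potency is reported as the *absolute* AC50 — the dose at which the fitted
curve crosses FC 0.5 (decreasing curve, c < 1) or FC 1.5 (increasing,
c > 1) — rather than the relative AC50 exp(e), because the absolute value
does not depend on how well the far asymptote c is pinned down by an
incomplete dose range. A delta-method standard error on log10(AC50) above
0.3 (i.e. log10 2) marks the estimate as uncertain ("~").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .plate_io import ROLE_SAMPLE

D_ZERO_DOSE_PLATEAU = 1.0
DEFAULT_FC_RANGE = (0.8, 1.2)
DEFAULT_FC_LEVELS = (0.5, 1.5)  # decreasing, increasing
SE_UNCERTAIN_LOG10 = 0.3
_PARAM_FLOOR = 1e-6
_SIGMA2_FLOOR = 1e-12
_MODEL_RANK = {"constant": 0, "pl3": 1, "pl3_weighted": 2}


def log_logistic(x, b: float, c: float, e: float, d: float = D_ZERO_DOSE_PLATEAU):
    """Three-parameter log-logistic mean function; f(0) = d exactly (limit
    convention for b > 0, where log 0 -> -inf sends the logistic term to 1)."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(d))
    pos = x > 0
    with np.errstate(over="ignore"):
        z = b * (np.log(x[pos]) - e)
        out[pos] = c + (d - c) / (1.0 + np.exp(z))
    return out if out.shape else float(out)


@dataclass
class DoseSeries:
    gene: str
    compound: str
    x: np.ndarray  # doses, >= 0
    y: np.ndarray  # observed FC, finite, >= 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y) or len(self.x) == 0:
            raise ValidationError("dose series needs matching nonempty x and y")
        if not np.all(np.isfinite(self.y)) or np.any(self.x < 0):
            raise ValidationError("doses must be >= 0 and FC finite")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_distinct_nonzero_doses(self) -> int:
        return len(np.unique(self.x[self.x > 0]))


@dataclass
class ModelFit:
    gene: str
    compound: str
    kind: str  # constant | pl3 | pl3_weighted
    params: dict = field(default_factory=dict)  # b, c, e_tilde (3PL) or level
    se: dict = field(default_factory=dict)
    cov: np.ndarray | None = None  # 3x3 over (b, c, e_tilde)
    sigma2: float = float("nan")
    aic: float = float("nan")
    n: int = 0
    converged: bool = True
    ac50_abs: float | None = None
    log10_ac50: float | None = None
    se_log10_ac50: float | None = None
    uncertain: bool = False
    ac50_note: str | None = None
    fc_at_max: float | None = None
    observed_max_fc: float | None = None
    direction: str | None = None  # increasing | decreasing | flat
    cytotox: bool = False
    cytotox_doses: list = field(default_factory=list)

    def predict(self, x):
        if self.kind == "constant":
            x = np.asarray(x, dtype=float)
            lvl = np.full(x.shape, self.params["level"])
            return lvl if lvl.shape else float(lvl)
        return log_logistic(x, self.params["b"], self.params["c"], self.params["e_tilde"])


def _gaussian_aic(rss_w: float, n: int, k: int, log_w_sum: float = 0.0) -> float:
    """AIC of a (weighted) Gaussian least-squares fit with sigma^2 profiled out.

    Weights are treated as fixed, known variance ratios: Var(y_i) = sigma^2 / w_i,
    giving loglik = -n/2 log(2 pi sigma_hat^2) + 1/2 sum(log w) - n/2 with
    sigma_hat^2 = sum(w r^2)/n. k counts mean parameters + sigma.
    """
    sigma2 = max(rss_w / n, _SIGMA2_FLOOR)
    return n * (math.log(2 * math.pi * sigma2) + 1.0) - log_w_sum + 2 * k


def fit_constant(series: DoseSeries) -> ModelFit:
    """Intercept-only Gaussian fit: level = mean FC, no dose dependence, no AC50."""
    level = float(series.y.mean())
    rss = float(((series.y - level) ** 2).sum())
    sigma2 = max(rss / series.n, _SIGMA2_FLOOR)
    aic = _gaussian_aic(rss, series.n, k=2)
    return ModelFit(
        gene=series.gene,
        compound=series.compound,
        kind="constant",
        params={"level": level},
        se={"level": math.sqrt(sigma2 / series.n)},
        sigma2=sigma2,
        aic=aic,
        n=series.n,
        observed_max_fc=float(series.y.max()),
    )


def _weights(series: DoseSeries) -> np.ndarray:
    """1/FC^2 weights; an FC of exactly 0 receives the largest finite weight
    in the series (dropping the strongest responses would be worse)."""
    y = series.y
    w = np.empty_like(y)
    pos = y > 0
    w[pos] = 1.0 / y[pos] ** 2
    if (~pos).any():
        if not pos.any():
            raise FitError("all FC values are 0; weighted fit undefined")
        warnings.warn(f"{series.gene}/{series.compound}: FC of 0, assigned max finite weight")
        w[~pos] = w[pos].max()
    return w


def _starts(series: DoseSeries) -> list[tuple[float, float, float]]:
    doses = np.unique(series.x[series.x > 0])
    cmin = max(float(series.y.min()), _PARAM_FLOOR)
    cmax = max(float(series.y.max()), _PARAM_FLOOR)
    return [
        (b0, c0, float(np.log(d)))
        for d in doses
        for b0 in (0.5, 1.0, 2.0)
        for c0 in (cmin, cmax)
    ]


def fit_3pl(series: DoseSeries, weighted: bool = False) -> ModelFit:
    """Multi-start bounded nonlinear least squares for the 3PL model.

    Minimizes sum w_i (y_i - f(x_i; b, c, e))^2 over b, c >= 1e-6 and free e
    (d fixed at 1; x = 0 contributes f = 1). Starts span log of every tested
    nonzero dose, b in {0.5, 1, 2} and c at the observed FC extremes. The
    covariance comes from the Jacobian at the optimum with the unbiased
    residual variance RSS_w / (n - 3).
    """
    if series.n_distinct_nonzero_doses < 2:
        raise FitError(
            f"{series.gene}/{series.compound}: 3PL needs >= 2 distinct nonzero doses"
        )
    w = _weights(series) if weighted else np.ones(series.n)
    sw = np.sqrt(w)
    x, y = series.x, series.y

    def resid(theta):
        b, c, e = theta
        return sw * (y - log_logistic(x, b, c, e))

    lb = [_PARAM_FLOOR, _PARAM_FLOOR, -np.inf]
    ub = [np.inf, np.inf, np.inf]
    # coarse pass over all starts, then one tightly-converged polish of the best
    best = None
    for theta0 in _starts(series):
        try:
            sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf",
                                ftol=1e-8, xtol=1e-8, max_nfev=300)
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18:
            break
    if best is not None:
        try:
            polished = least_squares(resid, best.x, bounds=(lb, ub), method="trf",
                                     ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=2000)
            if np.isfinite(polished.cost) and polished.cost <= best.cost:
                best = polished
        except Exception:
            pass
    kind = "pl3_weighted" if weighted else "pl3"
    if best is None:
        return ModelFit(series.gene, series.compound, kind, converged=False, n=series.n,
                        ac50_note="fit_failed", observed_max_fc=float(y.max()))
    b, c, e = (float(v) for v in best.x)
    rss_w = float(2 * best.cost)
    sigma2 = max(rss_w / series.n, _SIGMA2_FLOOR)
    aic = _gaussian_aic(rss_w, series.n, k=4, log_w_sum=float(np.log(w).sum()))
    cov = None
    se = {}
    if series.n > 3:
        jtj = best.jac.T @ best.jac
        try:
            cov = max(rss_w / (series.n - 3), _SIGMA2_FLOOR) * np.linalg.inv(jtj)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = dict(zip(("b", "c", "e_tilde"), np.sqrt(diag)))
            else:
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    return ModelFit(
        gene=series.gene,
        compound=series.compound,
        kind=kind,
        params={"b": b, "c": c, "e_tilde": e},
        se=se,
        cov=cov,
        sigma2=sigma2,
        aic=aic,
        n=series.n,
        observed_max_fc=float(y.max()),
        direction="decreasing" if c < 1 else ("increasing" if c > 1 else "flat"),
    )


def absolute_ac50(
    fit: ModelFit, fc_levels: tuple[float, float] = DEFAULT_FC_LEVELS
) -> tuple[float | None, float | None]:
    """Dose where the fitted curve crosses FC 0.5 (decreasing) / 1.5 (increasing).

    Closed form: log(AC50_abs) = e + (1/b) * log((d - L) / (L - c)) with
    d = 1, which is defined iff the target level L lies strictly between the
    asymptotes (c < 0.5 for a decreasing curve, c > 1.5 for increasing);
    otherwise the curve never reaches L and the AC50 is reported absent.
    The SE of log10(AC50) is propagated from cov(b, c, e) by the delta
    method; fits with no usable covariance are marked uncertain. Mutates and
    returns (ac50_abs, se_log10_ac50) on the fit.
    """
    if fit.kind == "constant" or not fit.converged:
        raise FitError("absolute AC50 is only defined for a converged 3PL fit")
    b, c, e = fit.params["b"], fit.params["c"], fit.params["e_tilde"]
    d = D_ZERO_DOSE_PLATEAU
    lvl_dec, lvl_inc = fc_levels
    if c == d:
        fit.ac50_note = "flat curve (c = d)"
        return None, None
    level = lvl_dec if c < d else lvl_inc
    ratio = (d - level) / (level - c)
    if ratio <= 0:
        fit.ac50_note = "level not reached"
        fit.ac50_abs = fit.log10_ac50 = fit.se_log10_ac50 = None
        return None, None
    log_ac50 = e + math.log(ratio) / b
    fit.ac50_abs = math.exp(log_ac50)
    fit.log10_ac50 = log_ac50 / math.log(10.0)
    if fit.cov is not None:
        grad = np.array([-math.log(ratio) / b**2, (1.0 / b) / (level - c), 1.0])
        var = float(grad @ fit.cov @ grad)
        if var >= 0:
            fit.se_log10_ac50 = math.sqrt(var) / math.log(10.0)
    fit.uncertain = fit.se_log10_ac50 is None or fit.se_log10_ac50 > SE_UNCERTAIN_LOG10
    return fit.ac50_abs, fit.se_log10_ac50


def fc_at_max(fit: ModelFit, x_max: float) -> float:
    """Model-predicted FC at the maximal tested dose (constant fit: its level)."""
    val = float(np.asarray(fit.predict(np.array([x_max])))[0])
    fit.fc_at_max = val
    return val


def select_model(
    series: DoseSeries,
    fc_range: tuple[float, float] = DEFAULT_FC_RANGE,
    fc_levels: tuple[float, float] = DEFAULT_FC_LEVELS,
) -> ModelFit:
    """Fixed model-selection scheme with AIC.

    All FC inside [0.8, 1.2] -> the response is uninformative, a constant fit
    is returned and no sigmoid is attempted. Otherwise constant, 3PL and
    weighted 3PL are fitted and the lowest AIC wins; exact ties prefer the
    simpler model (constant < 3PL < weighted 3PL). The winner gets its
    absolute AC50 (3PL kinds) and predicted FC at the top tested dose.
    """
    lo, hi = fc_range
    x_max = float(series.x.max())
    if np.all((series.y >= lo) & (series.y <= hi)):
        fit = fit_constant(series)
        fit.ac50_note = "uninformative (all FC within range)"
        fc_at_max(fit, x_max)
        return fit
    candidates = [fit_constant(series)]
    if series.n_distinct_nonzero_doses >= 2:
        for weighted in (False, True):
            try:
                cand = fit_3pl(series, weighted=weighted)
            except FitError:
                continue
            if cand.converged:
                candidates.append(cand)
    fit = min(candidates, key=lambda f: (f.aic, _MODEL_RANK[f.kind]))
    if fit.kind != "constant":
        absolute_ac50(fit, fc_levels)
    fc_at_max(fit, x_max)
    return fit


def build_series(
    fc: pd.DataFrame, annotations: pd.DataFrame, genes=None
) -> list[DoseSeries]:
    """One DoseSeries per gene x compound from sample-well fold changes.

    Replicate wells at the same dose are kept as individual points.
    """
    sample = [w for w in fc.index if annotations.at[w, "role"] == ROLE_SAMPLE]
    genes = list(fc.columns) if genes is None else list(genes)
    series = []
    for cpd, wells in pd.Series(sample, index=sample).groupby(
        annotations.loc[sample, "compound"]
    ):
        idx = list(wells.index)
        x = annotations.loc[idx, "concentration"].to_numpy(dtype=float)
        for g in genes:
            y = fc.loc[idx, g].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() == 0:
                continue
            series.append(DoseSeries(gene=g, compound=str(cpd), x=x[ok], y=y[ok]))
    return series


def analyze_dose_responses(
    fc: pd.DataFrame,
    annotations: pd.DataFrame,
    hkg_names=(),
    fc_range: tuple[float, float] = DEFAULT_FC_RANGE,
    fc_levels: tuple[float, float] = DEFAULT_FC_LEVELS,
) -> list[ModelFit]:
    """Model selection for every target gene x compound (HKG are not fitted)."""
    genes = [g for g in fc.columns if g not in set(hkg_names)]
    fits = []
    for s in build_series(fc, annotations, genes=genes):
        try:
            fits.append(select_model(s, fc_range=fc_range, fc_levels=fc_levels))
        except FitError as exc:
            warnings.warn(f"{s.gene}/{s.compound}: {exc}")
    return fits
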