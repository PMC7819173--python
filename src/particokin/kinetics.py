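"""Pulmonary clearance kinetics: one-phase and two-phase retention models.

The retained lung burden after the end of exposure is modelled as

    one-phase:  M(t) = P1 * exp(-lambda1 * t)
    two-phase:  M(t) = P1 * exp(-lambda1 * t) + P2 * exp(-lambda2 * t)

with t in days since the PEO-1 baseline, P1 (+ P2 = 1 when constrained) the
compartment fractions and lambda the per-day clearance rate constants; the
retention half-time of a compartment is T1/2 = ln(2) / lambda.  Biopersistent
particles (e.g. gold nanoparticles) follow the one-phase model — alveolar
macrophage-mediated mechanical clearance — while biosoluble particles (e.g.
silver nanoparticles) show an additional fast dissolution phase and need the
two-phase model.

The models are exposed as scikit-learn style estimators
(:class:`OnePhaseClearance`, :class:`TwoPhaseClearance`) fitting ``(t, y)``
retention data, plus an independent 3-point constrained solver
(:func:`exact_constrained_solve`) used as a cross-check: with the fast
fraction fixed and observations at exactly two post-baseline times, the
two-phase model reduces to a 2x2 nonlinear system solved by root bracketing.

With only three retention timepoints the unconstrained two-phase model is
underdetermined (three free parameters, two informative points); a fixed
compartment fraction must be supplied, mirroring how sparse regulatory-style
post-exposure designs are analysed in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import linregress
from sklearn.base import BaseEstimator

__all__ = [
    "RetentionSeries",
    "FitConfig",
    "OnePhaseClearance",
    "TwoPhaseClearance",
    "fit_one_phase",
    "fit_two_phase",
    "exact_constrained_solve",
    "half_time",
    "predict_retention",
    "fraction_cleared_by",
    "select_model",
    "IdentifiabilityError",
    "FitFailureError",
]

LN2 = float(np.log(2.0))


class IdentifiabilityError(ValueError):
    """Model has more free parameters than the data can pin down."""


class FitFailureError(RuntimeError):
    """Optimiser failed to converge from every start."""


def half_time(lam: float) -> float:
    """Retention half-time T1/2 = ln(2) / lambda, days (lambda per day)."""
    if lam <= 0:
        raise ValueError("clearance rate must be > 0")
    return LN2 / lam


@dataclass(frozen=True)
class RetentionSeries:
    """Retention observations on the post-exposure time axis.

    times are days since the PEO-1 baseline (times[0] = 0, strictly
    increasing); values are retained fractions (baseline = 1) or masses in ng,
    per ``scale``.
    """

    times: tuple
    values: tuple
    analyte: str = ""
    exposure_mode: str = "single"  # {'single', 'co'}
    scale: str = "fraction"  # {'fraction', 'mass'}

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("need >= 2 matched (time, value) points")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if np.any(v <= 0):
            raise ValueError("retention values must be > 0")
        if self.scale == "fraction" and not np.isclose(v[0], 1.0):
            raise ValueError("fraction-scale series must start at 1.0")
        if self.scale not in ("fraction", "mass"):
            raise ValueError(f"unknown scale {self.scale!r}")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Fitting options shared by the convenience wrappers.

    objective_scale: 'log' linearises the one-phase model (default there);
    the two-phase model is always fit on the natural scale so the compartment
    fractions stay interpretable.  ``fraction_constraint`` fixes the fast
    fraction P1 of the two-phase model.
    """

    objective_scale: str = "log"
    amplitude: str = "free"  # {'free', 'fixed_1'}
    fraction_constraint: float | None = None
    multistart_count: int = 16
    seed: int = 0
    lambda_bounds: tuple = (1e-6, 10.0)

    def __post_init__(self) -> None:
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")
        lo, hi = self.lambda_bounds
        if not (0 < lo < hi):
            raise ValueError("lambda bounds must be positive and ordered")


def _validate_ty(t, y):
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 matched (t, y) points")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any(y <= 0):
        raise ValueError("retention values must be > 0")
    order = np.argsort(t)
    return t[order], y[order]


class OnePhaseClearance(BaseEstimator):
    """First-order (one-compartment) clearance model M(t) = P1 exp(-l1 t).

    Parameters
    ----------
    amplitude : {'free', 'fixed_1'}
        'free' estimates P1 alongside the rate; 'fixed_1' pins P1 = 1
        (the one-compartment convention for fraction-scale data).
    objective_scale : {'log', 'linear'}
        'log' (default) fits by least squares on log-retention, which makes
        the model a straight line; 'linear' fits on the natural scale.

    Attributes
    ----------
    p1_ : float
        Fitted (or fixed) amplitude.
    lambda1_ : float
        Clearance rate constant, per day.
    half_time_ : float
        ln(2)/lambda1_, days.
    sse_ : float
        Sum of squared residuals on the fitted objective scale.
    sse_linear_ : float
        Sum of squared residuals on the natural scale (for model comparison).
    """

    def __init__(self, amplitude: str = "free", objective_scale: str = "log"):
        self.amplitude = amplitude
        self.objective_scale = objective_scale

    def fit(self, t, y):
        t, y = _validate_ty(t, y)
        if self.amplitude not in ("free", "fixed_1"):
            raise ValueError(f"unknown amplitude mode {self.amplitude!r}")
        if self.objective_scale not in ("log", "linear"):
            raise ValueError(f"unknown objective scale {self.objective_scale!r}")
        if self.objective_scale == "log":
            ly = np.log(y)
            if self.amplitude == "free":
                res = linregress(t, ly)
                lam, p1 = -float(res.slope), float(np.exp(res.intercept))
            else:
                # regression through the origin of log space
                lam = -float(np.sum(t * ly) / np.sum(t * t))
                p1 = 1.0
            resid = ly - (np.log(p1) - lam * t)
        else:
            p0 = [y[0], 0.1] if self.amplitude == "free" else [0.1]

            def model(params):
                if self.amplitude == "free":
                    a, lam = params
                else:
                    a, lam = 1.0, params[0]
                return a * np.exp(-lam * t)

            sol = least_squares(lambda p: model(p) - y, p0,
                                bounds=(0, np.inf), method="trf")
            if not sol.success:
                raise FitFailureError("one-phase linear-scale fit failed")
            if self.amplitude == "free":
                p1, lam = (float(sol.x[0]), float(sol.x[1]))
            else:
                p1, lam = 1.0, float(sol.x[0])
            resid = model(sol.x) - y
        if lam <= 0:
            raise FitFailureError(
                f"estimated clearance rate is non-positive ({lam:.4g}/d): "
                "retention does not decline over the series")
        self.p1_ = p1
        self.lambda1_ = lam
        self.half_time_ = half_time(lam)
        self.sse_ = float(np.sum(resid**2))
        self.sse_linear_ = float(np.sum((p1 * np.exp(-lam * t) - y) ** 2))
        self.n_points_ = t.size
        self.n_params_ = 2 if self.amplitude == "free" else 1
        return self

    @classmethod
    def from_parameters(cls, lambda1: float, p1: float = 1.0) -> "OnePhaseClearance":
        """Build an already-parameterised model (e.g. from published values)
        for plug-in prediction."""
        est = cls(amplitude="fixed_1" if p1 == 1.0 else "free")
        est.p1_ = float(p1)
        est.lambda1_ = float(lambda1)
        est.half_time_ = half_time(lambda1)
        est.sse_ = est.sse_linear_ = float("nan")
        est.n_points_ = 0
        est.n_params_ = 1 if p1 == 1.0 else 2
        return est

    def predict(self, t):
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        out = self.p1_ * np.exp(-self.lambda1_ * t)
        return float(out) if out.ndim == 0 else out

    def _check_fitted(self):
        if not hasattr(self, "lambda1_"):
            raise AttributeError("model is not fitted yet; call fit(t, y)")

    def summary(self) -> dict:
        self._check_fitted()
        return {"model": "one-phase", "p1": self.p1_, "lambda1": self.lambda1_,
                "half_time_d": self.half_time_, "sse": self.sse_}


class TwoPhaseClearance(BaseEstimator):
    """Biexponential clearance model M(t) = P1 exp(-l1 t) + P2 exp(-l2 t)
    with the constraint P1 + P2 = 1 and l1 > l2 (fast phase first).

    Parameters
    ----------
    fast_fraction : float or None
        Fix the fast-compartment fraction P1 (0 < P1 < 1).  Required when the
        series has only two informative (post-baseline) points; with None the
        fraction is estimated.
    multistart_count : int
        Number of multistart initial (l1, l2) pairs, log-spaced/jittered over
        ``lambda_bounds``; the best SSE wins.  Deterministic given ``seed``.
    seed : int
        Seed for the multistart jitter.
    lambda_bounds : (float, float)
        Box bounds on both rate constants, per day.

    Attributes
    ----------
    p1_, p2_ : float
        Fast and slow compartment fractions (sum to 1).
    lambda_fast_, lambda_slow_ : float
        Rate constants, per day, lambda_fast_ >= lambda_slow_.
    half_time_fast_, half_time_slow_ : float
        ln(2)/lambda, days.
    sse_ : float
        Natural-scale sum of squared residuals.
    """

    def __init__(self, fast_fraction: float | None = None,
                 multistart_count: int = 16, seed: int = 0,
                 lambda_bounds: tuple = (1e-6, 10.0)):
        self.fast_fraction = fast_fraction
        self.multistart_count = multistart_count
        self.seed = seed
        self.lambda_bounds = lambda_bounds

    def _starts(self) -> np.ndarray:
        lo, hi = self.lambda_bounds
        rng = np.random.default_rng(self.seed)
        # log-spaced backbone with mild jitter; first start is the plain grid
        m = self.multistart_count
        grid = np.exp(np.linspace(np.log(lo * 10), np.log(hi / 10), max(m, 2)))
        pairs = []
        for i in range(m):
            l1 = grid[i % grid.size]
            l2 = l1 / np.exp(rng.uniform(1.0, 6.0)) if i else l1 / 20.0
            pairs.append((max(l1, l2), max(min(l1, l2), lo)))
        return np.asarray(pairs)

    def fit(self, t, y):
        t, y = _validate_ty(t, y)
        p_fixed = self.fast_fraction
        if p_fixed is not None and not (0 < p_fixed < 1):
            raise ValueError("fast_fraction must be in (0, 1)")
        n_informative = int(np.sum(t > 0))
        n_free = 2 if p_fixed is not None else 3
        if n_informative < n_free:
            raise IdentifiabilityError(
                f"two-phase model has {n_free} free parameters but only "
                f"{n_informative} post-baseline points; fix the compartment "
                "split with fast_fraction (fraction_constraint) to proceed")
        lo, hi = self.lambda_bounds

        # parameterise the slow rate as a fraction of the fast one so the
        # ordering l1 >= l2 holds by construction and the fixed fraction is
        # unambiguously the FAST fraction (the swapped assignment is a
        # distinct exact solution of the constrained system)
        def unpack(x):
            if p_fixed is not None:
                p1, (l1, frac) = p_fixed, x
            else:
                p1, l1, frac = x
            return p1, l1, l1 * frac

        def resid(x):
            p1, l1, l2 = unpack(x)
            return (p1 * np.exp(-l1 * t) + (1 - p1) * np.exp(-l2 * t)) - y

        if p_fixed is not None:
            bounds = ([lo, 1e-9], [hi, 1.0])
        else:
            bounds = ([1e-6, lo, 1e-9], [1 - 1e-6, hi, 1.0])
        best = None
        for l1_0, l2_0 in self._starts():
            frac_0 = min(max(l2_0 / l1_0, 1e-9), 1.0)
            x0 = ([l1_0, frac_0] if p_fixed is not None
                  else [0.5, l1_0, frac_0])
            try:
                sol = least_squares(resid, x0, bounds=bounds, method="trf",
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                    max_nfev=10_000)
            except Exception:
                continue
            # status 0 = evaluation budget hit; keep the candidate, the best
            # SSE across starts still decides
            if sol.status < 0:
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, sol.x)
        if best is None:
            raise FitFailureError("two-phase fit failed from every start")
        sse, x = best
        p1, l1, l2 = unpack(x)
        p2 = 1.0 - p1
        if l1 < l2:  # enforce fast-first ordering
            l1, l2 = l2, l1
            p1, p2 = p2, p1
        self.p1_, self.p2_ = float(p1), float(p2)
        self.lambda_fast_, self.lambda_slow_ = float(l1), float(l2)
        self.half_time_fast_ = half_time(self.lambda_fast_)
        self.half_time_slow_ = half_time(self.lambda_slow_)
        self.sse_ = sse
        self.sse_linear_ = sse
        self.n_points_ = t.size
        self.n_params_ = n_free
        return self

    @classmethod
    def from_parameters(cls, p1: float, lambda_fast: float,
                        lambda_slow: float) -> "TwoPhaseClearance":
        """Build an already-parameterised model (e.g. from published
        fraction/half-time values) for plug-in prediction."""
        if not (0 < p1 < 1):
            raise ValueError("p1 must be in (0, 1)")
        if not (lambda_fast >= lambda_slow > 0):
            raise ValueError("need lambda_fast >= lambda_slow > 0")
        est = cls(fast_fraction=p1)
        est.p1_, est.p2_ = float(p1), float(1 - p1)
        est.lambda_fast_ = float(lambda_fast)
        est.lambda_slow_ = float(lambda_slow)
        est.half_time_fast_ = half_time(lambda_fast)
        est.half_time_slow_ = half_time(lambda_slow)
        est.sse_ = est.sse_linear_ = float("nan")
        est.n_points_ = 0
        est.n_params_ = 2
        return est

    def predict(self, t):
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        out = (self.p1_ * np.exp(-self.lambda_fast_ * t)
               + self.p2_ * np.exp(-self.lambda_slow_ * t))
        return float(out) if out.ndim == 0 else out

    def _check_fitted(self):
        if not hasattr(self, "lambda_fast_"):
            raise AttributeError("model is not fitted yet; call fit(t, y)")

    def summary(self) -> dict:
        self._check_fitted()
        return {"model": "two-phase", "p1": self.p1_, "p2": self.p2_,
                "lambda1": self.lambda_fast_, "lambda2": self.lambda_slow_,
                "half_time_fast_d": self.half_time_fast_,
                "half_time_slow_d": self.half_time_slow_, "sse": self.sse_}


def fit_one_phase(series: RetentionSeries,
                  config: FitConfig = FitConfig()) -> OnePhaseClearance:
    """Fit the first-order model to a retention series (wrapper over
    :class:`OnePhaseClearance`)."""
    est = OnePhaseClearance(amplitude=config.amplitude,
                            objective_scale=config.objective_scale)
    return est.fit(series.t, series.y)


def fit_two_phase(series: RetentionSeries,
                  config: FitConfig = FitConfig()) -> TwoPhaseClearance:
    """Fit the biexponential model (natural scale, P1+P2=1) to a retention
    series (wrapper over :class:`TwoPhaseClearance`)."""
    est = TwoPhaseClearance(fast_fraction=config.fraction_constraint,
                            multistart_count=config.multistart_count,
                            seed=config.seed,
                            lambda_bounds=config.lambda_bounds)
    return est.fit(series.t, series.y)


def exact_constrained_solve(times, values, p1_fixed: float,
                            tol: float = 1e-12) -> TwoPhaseClearance:
    """Solve the fixed-fraction two-phase model exactly through a baseline
    plus two post-baseline points.

    With P1 fixed and observations y1, y2 at t1 < t2, the first equation gives
    lambda1 as a function of lambda2,

        exp(-l1 t1) = (y1 - (1 - P1) exp(-l2 t1)) / P1,

    leaving a single root-finding problem in lambda2, bracketed on
    (l2 where l1 -> inf, l2 where l1 = l2) and solved by Brent's method.
    Independent of the least-squares path; used as its oracle.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != 3 or y.size != 3:
        raise ValueError("exact solve needs exactly 3 points (baseline + 2)")
    if t[0] != 0 or not np.isclose(y[0], 1.0):
        raise ValueError("first point must be the baseline (0, 1)")
    if not (0 < p1_fixed < 1):
        raise ValueError("p1_fixed must be in (0, 1)")
    t1, t2 = float(t[1]), float(t[2])
    y1, y2 = float(y[1]), float(y[2])
    if not (t2 > t1 > 0):
        raise ValueError("times must be strictly increasing from 0")
    if not (0 < y2 < y1 < 1):
        raise ValueError("no two-phase solution: values must decline inside (0, 1)")
    p, q = p1_fixed, 1.0 - p1_fixed

    def lambda1_of(l2: float) -> float:
        fast_part = (y1 - q * np.exp(-l2 * t1)) / p
        if fast_part <= 0:
            return np.inf
        return -np.log(fast_part) / t1

    def g(l2: float) -> float:
        l1 = lambda1_of(l2)
        if np.isinf(l1):
            return q * np.exp(-l2 * t2) - y2
        return p * np.exp(-l1 * t2) + q * np.exp(-l2 * t2) - y2

    # l2 upper limit: l1 == l2 <=> exp(-l2 t1) = y1
    l2_hi = -np.log(y1) / t1
    # l2 lower limit: fast term vanishes (l1 -> inf) when q exp(-l2 t1) = y1
    l2_lo = (-np.log(y1 / q) / t1) if y1 < q else 0.0
    eps = 1e-13
    a, b = l2_lo + eps, l2_hi - eps
    ga, gb = g(a), g(b)
    if ga * gb > 0:
        if abs(gb) < 1e-9:
            # generating rates coincide: the root sits on the l1 == l2
            # boundary of the bracket (one-phase collapse)
            l2 = l2_hi
        else:
            raise ValueError(
                "no bracketing solution for the constrained two-phase "
                "system; the observed decline is inconsistent with the "
                "fixed fraction")
    else:
        l2 = brentq(g, a, b, xtol=tol, rtol=8 * np.finfo(float).eps)
    l1 = lambda1_of(l2)
    if np.isinf(l1):
        raise ValueError("degenerate solution: fast rate unbounded")
    fit = TwoPhaseClearance(fast_fraction=p1_fixed)
    fit.p1_, fit.p2_ = p, q
    fit.lambda_fast_, fit.lambda_slow_ = float(max(l1, l2)), float(min(l1, l2))
    fit.half_time_fast_ = half_time(fit.lambda_fast_)
    fit.half_time_slow_ = half_time(fit.lambda_slow_)
    pred = fit.predict(t)
    fit.sse_ = float(np.sum((pred - y) ** 2))
    fit.sse_linear_ = fit.sse_
    fit.n_points_ = 3
    fit.n_params_ = 2
    return fit


def predict_retention(fit, t):
    """Model-predicted retained fraction at time t >= 0 days."""
    return fit.predict(t)


def fraction_cleared_by(fit, t) -> float:
    """Percent of the baseline burden cleared by day t:
    100 * (1 - M(t))."""
    pred = predict_retention(fit, t)
    out = 100.0 * (1.0 - np.asarray(pred))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelSelection:
    """AICc comparison of the two clearance models plus any a-priori choice."""

    aicc_one: float
    aicc_two: float
    aicc_reliable: bool
    aicc_choice: str
    a_priori: str | None
    chosen: str
    note: str = ""


def _aicc(sse: float, n: int, k_model: int) -> tuple[float, bool]:
    """Small-sample AIC for a least-squares fit; k counts the kinetic
    parameters plus the residual variance."""
    k = k_model + 1
    if sse <= 0:
        sse = np.finfo(float).tiny
    aic = n * np.log(sse / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return float(aic), False
    return float(aic + 2 * k * (k + 1) / denom), True


def select_model(one: OnePhaseClearance, two: TwoPhaseClearance,
                 a_priori: str | None = None) -> ModelSelection:
    """Compare fitted one- and two-phase models on the same series.

    Uses natural-scale SSE AICc; with 3-point series the correction term is
    undefined and AICc is flagged unreliable, in which case an a-priori model
    choice (e.g. one-phase for biopersistent, two-phase for biosoluble
    particles) is required and takes precedence.  When given, the a-priori
    choice always wins; AICc values are still reported.
    """
    n = one.n_points_
    if two.n_points_ != n:
        raise ValueError("both fits must be on the same series")
    a1, r1 = _aicc(one.sse_linear_, n, one.n_params_)
    a2, r2 = _aicc(two.sse_linear_, n, two.n_params_)
    reliable = r1 and r2
    aicc_choice = "one-phase" if a1 <= a2 else "two-phase"
    if a_priori is not None:
        if a_priori not in ("one-phase", "two-phase"):
            raise ValueError("a_priori must be 'one-phase' or 'two-phase'")
        chosen, note = a_priori, "a-priori model choice applied"
    elif reliable:
        chosen, note = aicc_choice, "selected by AICc"
    else:
        raise IdentifiabilityError(
            "AICc is unreliable at this sample size (n - k - 1 <= 0); "
            "supply an a-priori model choice")
    return ModelSelection(aicc_one=a1, aicc_two=a2, aicc_reliable=reliable,
                          aicc_choice=aicc_choice, a_priori=a_priori,
                          chosen=chosen, note=note)


def retention_series_from_table(retention: "pd.DataFrame", analyte: str = "",
                                exposure_mode: str = "single") -> RetentionSeries:
    """Build a fraction-scale series from a retention table (as produced by
    :func:`particokin.burden.retention_percent`)."""
    import pandas as pd  # noqa: F401  (narrow import; table hand-off only)

    tab = retention.sort_values("days")
    return RetentionSeries(times=tuple(tab["days"].astype(float)),
                           values=tuple(tab["retention_pct"].astype(float) / 100.0),
                           analyte=analyte, exposure_mode=exposure_mode)
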