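"""First-order one-compartment bioconcentration model: simulation and fitting.

The model describes uptake of a waterborne chemical into a small aquatic
organism with first-order kinetics:

    dCf/dt = k1 * Cw(t) - k2 * Cf        (uptake phase)
    dCf/dt = -k2 * Cf                    (depuration phase)

where ``Cf`` is the body burden (ng/g wet weight), ``Cw`` the water
concentration (ug/L), ``k1`` the uptake rate constant (L kg^-1 h^-1) and
``k2`` the elimination rate constant (h^-1).  With ``Cf(0) = 0`` and constant
water concentration the uptake phase has the closed form

    Cf(t) = (k1/k2) * Cw * (1 - exp(-k2 t))

whose plateau ``(k1/k2) * Cw`` defines the kinetic bioconcentration factor
``BCF_k = k1/k2`` (L/kg).  The steady-state estimate ``BCF_48h`` is the ratio
of the body burden at the end of exposure to the mean water concentration.

Fitting exploits that for fixed ``k2`` the model is linear in ``k1``
(variable projection): ``k1`` has a closed-form least-squares solution, so
the two-parameter fit reduces to a robust 1-D search over ``log k2`` (coarse
log-spaced grid followed by bounded Brent refinement).  The search is exposed
as the scikit-learn-compatible estimator :class:`FirstOrderUptakeModel`;
:func:`fit_first_order` wraps it for :class:`ConcentrationSeries` inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedPlateauError,
)
from .series import ConcentrationSeries

__all__ = [
    "predict_uptake",
    "predict_depuration",
    "FirstOrderUptakeModel",
    "KineticFit",
    "fit_first_order",
    "bcf_kinetic",
    "bcf_steady_state",
    "SteadyStateResult",
    "detect_steady_state",
    "BootstrapResult",
    "bootstrap_uncertainty",
]


# ---------------------------------------------------------------------------
# closed-form kinetics
# ---------------------------------------------------------------------------

def _uptake_shape(t, k2):
    """(1 - exp(-k2 t)) / k2, with the k2 -> 0 limit t handled exactly."""
    t = np.asarray(t, dtype=float)
    if k2 == 0.0:
        return t.copy()
    return -np.expm1(-k2 * t) / k2


def _check_nonneg(**kwargs):
    for key, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidInputError(f"{key} must be finite and >= 0, got {value!r}")


def predict_uptake(k1, k2, cw, t):
    """Body burden during uptake under constant water concentration.

    ``Cf(t) = (k1/k2) * cw * (1 - exp(-k2 t))``; for ``k2 == 0`` the exact
    limit ``k1 * cw * t`` is returned (no division by zero).

    Parameters
    ----------
    k1 : float
        Uptake rate constant, L kg^-1 h^-1.
    k2 : float
        Elimination rate constant, h^-1.
    cw : float
        Water concentration, ug/L.
    t : float or array-like
        Exposure time(s), hours.

    Returns
    -------
    float or ndarray
        Body burden in ng/g wet weight.
    """
    _check_nonneg(k1=k1, k2=k2, cw=cw, t=t)
    out = k1 * cw * _uptake_shape(t, k2)
    return float(out) if np.ndim(t) == 0 else out


def predict_depuration(cf0, k2, t):
    """Body burden during depuration: ``cf0 * exp(-k2 t)`` (ng/g)."""
    _check_nonneg(cf0=cf0, k2=k2, t=t)
    out = cf0 * np.exp(-k2 * np.asarray(t, dtype=float))
    return float(out) if np.ndim(t) == 0 else out


def _step_uptake_response(t_eval, k2, step_times, step_values):
    """Per-unit-k1 body burden for piecewise-constant water concentration.

    Integrates ``dX/dt = cw(t) - k2 X`` segment-analytically, where ``cw``
    holds ``step_values[i]`` from ``step_times[i]`` to ``step_times[i+1]``
    (the first value extends back to 0, the last forward indefinitely).
    """
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    step_times = np.asarray(step_times, dtype=float)
    step_values = np.asarray(step_values, dtype=float)
    bounds = np.concatenate([[0.0], step_times[1:], [np.inf]])
    out = np.empty_like(t_eval)
    for j, t in enumerate(t_eval):
        x = 0.0
        for i, c in enumerate(step_values):
            a, b = bounds[i], min(bounds[i + 1], t)
            if b <= a:
                continue
            dt = b - a
            if k2 == 0.0:
                x += c * dt
            else:
                e = math.exp(-k2 * dt)
                x = x * e + c * (1.0 - e) / k2
            if b >= t:
                break
        out[j] = x
    return out


# ---------------------------------------------------------------------------
# variable-projection core
# ---------------------------------------------------------------------------

def _varpro_search(t, y, response, k2_bounds, n_grid):
    """Minimize SSE over (k1 >= 0, k2 in bounds) with k1 profiled out.

    ``response(t, k2)`` is the model per unit k1.  Returns
    ``(k1, k2, sse, converged)``.  Grid ties resolve to the lowest k2
    (ascending grid + first argmin); a best-fit pinned at a grid boundary is
    reported with ``converged=False``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = k2_bounds
    if not (0 < lo < hi):
        raise InvalidInputError(f"k2 bounds must satisfy 0 < lo < hi, got {k2_bounds}")

    def profiled(k2):
        g = response(t, k2)
        den = float(g @ g)
        k1 = max(0.0, float(g @ y) / den) if den > 0 else 0.0
        r = y - k1 * g
        return k1, float(r @ r)

    logs = np.linspace(math.log(lo), math.log(hi), n_grid)
    sses = np.array([profiled(math.exp(lg))[1] for lg in logs])
    i = int(np.argmin(sses))
    bracket = (logs[max(i - 1, 0)], logs[min(i + 1, n_grid - 1)])
    res = minimize_scalar(
        lambda lg: profiled(math.exp(lg))[1],
        bounds=bracket, method="bounded", options={"xatol": 1e-12},
    )
    best_log = logs[i]
    best_sse = sses[i]
    if res.success and res.fun <= best_sse:
        best_log, best_sse = float(res.x), float(res.fun)
    k2 = math.exp(best_log)
    k1, sse = profiled(k2)
    interior = 0 < i < n_grid - 1
    converged = bool(res.success) and (interior or k1 == 0.0)
    return k1, k2, sse, converged


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class FirstOrderUptakeModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the one-compartment uptake curve.

    The design matrix ``X`` holds a single column of exposure times (hours);
    ``y`` holds the matching body burdens (ng/g).  The water concentration
    enters as a parameter: either a constant ``cw`` (the mean measured
    exposure concentration) or a piecewise-constant profile ``cw_profile``.

    Parameters
    ----------
    cw : float, optional
        Constant water concentration (ug/L).  Required unless
        ``cw_profile`` is given.
    cw_profile : tuple of (times, values), optional
        Step profile of the water concentration; activates numerical
        (segment-analytic) integration of the governing ODE instead of the
        constant-``cw`` closed form.
    weighting : {"none", "inverse_yhat"}
        ``"none"`` minimizes unweighted squared residuals on raw
        concentrations; ``"inverse_yhat"`` down-weights large predictions by
        1/yhat (refined with a derivative-based least-squares pass).
    k2_bounds : tuple of float
        Search range for the elimination rate constant (h^-1).
    n_grid : int
        Size of the log-spaced k2 grid that seeds the 1-D refinement.

    Attributes
    ----------
    k1_ : float
        Fitted uptake rate constant (L kg^-1 h^-1).
    k2_ : float
        Fitted elimination rate constant (h^-1).
    bcf_k_ : float
        Kinetic bioconcentration factor ``k1_/k2_`` (L/kg).
    sse_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
        Honest convergence flag (False when the optimum sticks to a search
        boundary).
    """

    def __init__(self, cw=None, cw_profile=None, weighting="none",
                 k2_bounds=(1e-5, 10.0), n_grid=60):
        self.cw = cw
        self.cw_profile = cw_profile
        self.weighting = weighting
        self.k2_bounds = k2_bounds
        self.n_grid = n_grid

    def _response(self):
        if self.cw_profile is not None:
            times, values = self.cw_profile
            return lambda t, k2: _step_uptake_response(t, k2, times, values)
        if self.cw is None:
            raise InvalidInputError("either cw or cw_profile must be provided")
        cw = float(self.cw)
        return lambda t, k2: cw * _uptake_shape(t, k2)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True, ensure_min_samples=3)
        if X.shape[1] != 1:
            raise InvalidInputError("X must hold a single column of times (hours)")
        t = X[:, 0]
        if np.any(t < 0):
            raise InvalidInputError("exposure times must be >= 0")
        if len(np.unique(t[t > 0])) < 2:
            raise InsufficientDataError(
                "need at least 2 distinct positive times to identify (k1, k2)"
            )
        if self.weighting not in ("none", "inverse_yhat"):
            raise InvalidInputError(f"unknown weighting {self.weighting!r}")
        response = self._response()
        k1, k2, sse, converged = _varpro_search(t, y, response, self.k2_bounds, self.n_grid)
        if self.weighting == "inverse_yhat":
            k1, k2, sse, converged = self._refine_weighted(t, y, response, k1, k2)
        self.k1_, self.k2_, self.sse_, self.converged_ = k1, k2, sse, converged
        self.bcf_k_ = k1 / k2 if k2 > 0 else math.inf
        self.n_points_ = len(t)
        return self

    def _refine_weighted(self, t, y, response, k1_0, k2_0):
        eps = max(np.mean(np.abs(y)) * 1e-9, 1e-12)

        def resid(theta):
            k1, k2 = np.exp(theta)
            f = k1 * response(t, k2)
            return (y - f) / np.sqrt(np.maximum(f, eps))

        theta0 = np.log([max(k1_0, 1e-12), k2_0])
        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        k1, k2 = np.exp(sol.x)
        f = k1 * response(t, k2)
        sse = float(np.sum((y - f) ** 2))
        return float(k1), float(k2), sse, bool(sol.success)

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.k1_ * self._response()(X[:, 0], self.k2_)


# ---------------------------------------------------------------------------
# series-level fitting API
# ---------------------------------------------------------------------------

@dataclass
class KineticFit:
    """Result of fitting the uptake model to one analyte's series."""

    analyte: str
    k1: float                  # L kg^-1 h^-1
    k2: float                  # h^-1
    cw_mean: float             # ug/L, arithmetic mean of uncensored water values
    bcf_k: float               # L/kg
    bcf_48h: float | None      # L/kg, None when t_end has no usable sample
    residual_sse: float
    converged: bool
    n_points_used: int
    intervals: dict | None = None
    notes: list[str] = field(default_factory=list)


def _fit_points(body: ConcentrationSeries, include_below_loq: bool = True):
    """Uptake-phase observations used for fitting: t > 0, quantitatively usable.

    Measured t=0 samples serve as controls/QC, never as fit data (the model
    fixes Cf(0) = 0).
    """
    usable = body.usable(include_below_loq)
    pts = usable[usable["time_h"] > 0]
    return pts["time_h"].to_numpy(), pts["value"].to_numpy()


def _water_step_profile(water: ConcentrationSeries):
    means = water.replicate_means()
    return means.index.to_numpy(), means.to_numpy()


def fit_first_order(body: ConcentrationSeries, water: ConcentrationSeries, *,
                    cw_mode: str = "mean", weighting: str = "none",
                    include_below_loq: bool = True,
                    k2_bounds=(1e-5, 10.0), n_grid: int = 60) -> KineticFit:
    """Estimate (k1, k2) and both BCFs from uptake-phase series.

    Parameters
    ----------
    body, water : ConcentrationSeries
        Organism burdens (ng/g) and exposure-medium concentrations (ug/L).
    cw_mode : {"mean", "stepwise"}
        ``"mean"`` treats the water concentration as constant at the
        arithmetic mean of the uncensored measurements (the standard
        assumption); ``"stepwise"`` integrates the model against a
        previous-value step interpolation of the measured profile.
    weighting : {"none", "inverse_yhat"}
    include_below_loq : bool
        Keep below-LOQ (but above-LOD) body burdens in the fit, flagged.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct usable uptake time points, or no uncensored
        water measurements.
    """
    t, y = _fit_points(body, include_below_loq)
    if len(np.unique(t)) < 3:
        raise InsufficientDataError(
            f"{body.analyte}: need >= 3 distinct uptake time points with usable "
            f"body burdens, have {len(np.unique(t))}"
        )
    water_vals = water.usable(include_below_loq=False)["value"].to_numpy()
    if len(water_vals) == 0:
        raise InsufficientDataError(f"{water.analyte}: no uncensored water measurements")
    cw_mean = float(np.mean(water_vals))

    if cw_mode == "mean":
        model = FirstOrderUptakeModel(cw=cw_mean, weighting=weighting,
                                      k2_bounds=k2_bounds, n_grid=n_grid)
    elif cw_mode == "stepwise":
        model = FirstOrderUptakeModel(cw_profile=_water_step_profile(water),
                                      weighting=weighting,
                                      k2_bounds=k2_bounds, n_grid=n_grid)
    else:
        raise InvalidInputError(f"unknown cw_mode {cw_mode!r}")
    model.fit(t.reshape(-1, 1), y)

    notes: list[str] = []
    if not model.converged_:
        notes.append("optimizer did not converge to an interior optimum")

    t_end = float(body.times.max())
    try:
        bcf48 = bcf_steady_state(body, water, t_end)
    except InsufficientDataError:
        bcf48 = None
        notes.append(f"no usable body burden at t_end={t_end} h; BCF_48h unavailable")

    return KineticFit(
        analyte=body.analyte,
        k1=model.k1_, k2=model.k2_, cw_mean=cw_mean,
        bcf_k=model.bcf_k_, bcf_48h=bcf48,
        residual_sse=model.sse_, converged=model.converged_,
        n_points_used=model.n_points_, notes=notes,
    )


def bcf_kinetic(k1: float, k2: float) -> float:
    """Kinetic bioconcentration factor ``k1/k2`` (L/kg)."""
    _check_nonneg(k1=k1, k2=k2)
    if k2 == 0:
        raise UndefinedPlateauError("k2 = 0: uptake curve has no plateau, BCF_k undefined")
    return k1 / k2


def bcf_steady_state(body: ConcentrationSeries, water: ConcentrationSeries,
                     t_end: float) -> float:
    """End-of-exposure BCF: mean body burden at ``t_end`` over mean water conc.

    Units: (ng/g) / (ug/L) = L/kg.
    """
    at_end = body.usable()[np.isclose(body.usable()["time_h"], t_end)]
    if len(at_end) == 0:
        raise InsufficientDataError(
            f"{body.analyte}: no usable body burden at t_end={t_end} h"
        )
    water_vals = water.usable(include_below_loq=False)["value"].to_numpy()
    if len(water_vals) == 0:
        raise InsufficientDataError(f"{water.analyte}: no uncensored water measurements")
    return float(at_end["value"].mean() / np.mean(water_vals))


# ---------------------------------------------------------------------------
# steady-state detection
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateResult:
    """Diagnostic outcome of the plateau check."""

    steady: bool
    relative_change: float        # |m_last - m_prev| / m_prev
    plateau_fraction: float | None  # estimated 1 - exp(-k2 t_end), if computable
    note: str = ""


def detect_steady_state(body: ConcentrationSeries,
                        tolerance: float = 0.20) -> SteadyStateResult:
    """Decide whether the body burden has plateaued by the end of exposure.

    Two conditions must hold:

    1. the replicate-mean burdens at the last two sampling times differ by at
       most ``tolerance`` (relative to the earlier mean), and
    2. when three or more positive-time means are available, a shape-only fit
       of ``B (1 - exp(-k2 t))`` estimates a plateau fraction
       ``1 - exp(-k2 t_end)`` of at least ``1 - tolerance``.

    The second condition guards against slow, nearly linear uptake whose last
    two samples happen to lie close together while the curve is still far
    from its plateau.  With only two time points it cannot be evaluated and
    the first condition decides alone.
    """
    means = body.replicate_means()
    if len(means) < 2:
        raise InsufficientDataError(
            f"{body.analyte}: need >= 2 distinct sampling times, have {len(means)}"
        )
    m_prev, m_last = float(means.iloc[-2]), float(means.iloc[-1])
    if m_prev > 0:
        rel = abs(m_last - m_prev) / m_prev
    else:
        rel = 0.0 if m_last == m_prev else math.inf
    steady = rel <= tolerance
    note = ""

    plateau_fraction = None
    pos = means[means.index > 0]
    if len(pos) >= 3:
        t = pos.index.to_numpy()
        y = pos.to_numpy()
        if np.any(y > 0):
            _, k2, _, _ = _varpro_search(
                t, y, lambda tt, kk: -np.expm1(-kk * tt), (1e-6, 10.0), 60
            )
            t_end = float(t.max())
            plateau_fraction = float(-np.expm1(-k2 * t_end))
            if plateau_fraction < 1.0 - tolerance:
                steady = False
                note = (f"uptake still rising: estimated plateau fraction "
                        f"{plateau_fraction:.2f} < {1 - tolerance:.2f}")
    return SteadyStateResult(steady=steady, relative_change=rel,
                             plateau_fraction=plateau_fraction, note=note)


# ---------------------------------------------------------------------------
# bootstrap uncertainty
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for the kinetic parameters."""

    level: float
    intervals: dict           # {"k1": (lo, hi), "k2": ..., "bcf_k": ...}
    n_success: int
    n_failed: int
    b: int
    samples: "np.ndarray"     # shape (n_success, 3): k1, k2, bcf_k
    warning: str | None = None


def bootstrap_uncertainty(body: ConcentrationSeries, water: ConcentrationSeries,
                          b: int = 200, seed: int = 0, level: float = 0.90,
                          **fit_kwargs) -> BootstrapResult:
    """Case-resampling bootstrap of the kinetic fit.

    Resamples the individual replicate measurement points of both series
    with replacement — the body-burden points that enter the fit and the
    uncensored water measurements behind the mean exposure concentration
    (BCF_k scales as 1/cw, so water-measurement error is a first-order
    variance component) — refits on each resample, and reports percentile
    intervals for ``k1``, ``k2`` and ``BCF_k``.  Deterministic for a fixed
    ``seed``; resamples on which the fit degenerates (fewer than two
    distinct positive times) are skipped and counted.
    """
    full = fit_first_order(body, water, **fit_kwargs)  # raises if unfittable
    include_below_loq = fit_kwargs.get("include_below_loq", True)
    t, y = _fit_points(body, include_below_loq)
    w = water.usable(include_below_loq=False)["value"].to_numpy()
    n = len(t)
    n_w = len(w)
    rng = np.random.default_rng(seed)

    warning = None
    if b < 100:
        warning = f"bootstrap with B={b} < 100 resamples: intervals unstable"
        warnings.warn(warning, stacklevel=2)

    model = FirstOrderUptakeModel(cw=full.cw_mean,
                                  weighting=fit_kwargs.get("weighting", "none"),
                                  k2_bounds=fit_kwargs.get("k2_bounds", (1e-5, 10.0)),
                                  n_grid=25)
    rows = []
    n_failed = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        ts, ys = t[idx], y[idx]
        cw_res = float(np.mean(w[rng.integers(0, n_w, size=n_w)]))
        if len(np.unique(ts)) < 2 or cw_res <= 0:
            n_failed += 1
            continue
        model.cw = cw_res
        try:
            model.fit(ts.reshape(-1, 1), ys)
        except (InsufficientDataError, InvalidInputError):
            n_failed += 1
            continue
        if not (math.isfinite(model.k1_) and math.isfinite(model.k2_)
                and math.isfinite(model.bcf_k_)):
            n_failed += 1
            continue
        rows.append((model.k1_, model.k2_, model.bcf_k_))

    if not rows:
        raise InsufficientDataError("all bootstrap resamples failed to fit")
    samples = np.asarray(rows)
    alpha = (1.0 - level) / 2.0
    names = ("k1", "k2", "bcf_k")
    intervals = {
        name: (float(np.quantile(samples[:, j], alpha)),
               float(np.quantile(samples[:, j], 1.0 - alpha)))
        for j, name in enumerate(names)
    }
    return BootstrapResult(level=level, intervals=intervals,
                           n_success=len(rows), n_failed=n_failed, b=b,
                           samples=samples, warning=warning)
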