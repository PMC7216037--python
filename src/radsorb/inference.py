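"""Coefficient fitting, χ²/WSOS-DF model discrimination, replicate stats.

Each rate law has a single free overall coefficient K once the
distribution coefficient is fixed from the equilibrium plateau, so the
"multidimensional" nonlinear regression collapses to a 1-D weighted
least-squares search.  The search runs over log10 K (bounded around a
moment-based initial guess) against the weighted sum of squares

    χ² = Σ_i (y_obs,i − y_pred,i)² / s_q,i²

and a fit is judged by WSOS/DF = χ²/(n_p − n): values in [0.1, 20]
(inclusive) mark an acceptable model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .curve import FRACTION_PCT, KineticCurve
from .errors import (
    DegenerateDataError,
    DegreesOfFreedomError,
    FitFailureError,
    IntegrationFailureError,
)
from .models import (
    MODEL_ORDER,
    ExperimentConditions,
    KineticModel,
    Q_DRIVEN,
    RateCoefficient,
    SorbentProperties,
    _scaled_solution,
)

__all__ = [
    "DEFAULT_SIGMA_REL",
    "DEFAULT_SIGMA_FLOOR_PCT",
    "FitResult",
    "ReplicateSummary",
    "default_uncertainty",
    "estimate_kd",
    "chi_square",
    "wsos_df",
    "fit_overall_coefficient",
    "select_model",
    "summarize_replicates",
]

DEFAULT_SIGMA_REL = 0.05
DEFAULT_SIGMA_FLOOR_PCT = 0.5
WSOS_DF_LOW = 0.1
WSOS_DF_HIGH = 20.0
_LOG10_BELOW = 6.0  # search decades below the initial guess
_LOG10_ABOVE = 3.0  # and above


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model's overall coefficient to one curve."""

    model: KineticModel
    K_printed: float  # fitted overall coefficient, cm³·g⁻¹·min⁻¹
    sigma: float  # 1-σ from the local χ² curvature (nan if not defined)
    chi2: float
    wsos_df: float
    n_p: int
    n: int
    n_d: int
    acceptable: bool
    identifiable: bool
    predicted: KineticCurve

    @property
    def coefficient(self) -> RateCoefficient:
        return RateCoefficient(self.model, self.K_printed)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and population standard deviation (σ_es, divide-by-N)."""

    values: tuple[float, ...]
    mean: float
    sigma_es: float


def default_uncertainty(
    y,
    sigma_rel: float = DEFAULT_SIGMA_REL,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR_PCT,
) -> np.ndarray:
    """Counting-dominated per-point uncertainty: max(σ_rel·y, floor)."""
    y = np.asarray(y, dtype=float)
    return np.maximum(sigma_rel * np.abs(y), sigma_floor)


def estimate_kd(
    curve: KineticCurve, r: float, *, window_start_min: float = 420.0
) -> float:
    """Distribution coefficient from the equilibrium plateau.

    Kd = r·f_eq/(1 − f_eq) with f_eq the mean sorbed fraction over the
    sampling points at or beyond ``window_start_min`` (default 7 h).
    """
    if curve.kind != FRACTION_PCT:
        raise ValueError("Kd estimation needs a sorbed-fraction curve")
    sel = curve.times >= window_start_min
    if not np.any(sel):
        sel = curve.times >= curve.times[-1]
    f_eq = float(np.mean(curve.y[sel])) / 100.0
    f_eq = min(max(f_eq, 0.0), 1.0 - 1e-12)
    return r * f_eq / (1.0 - f_eq)


def chi_square(observed: KineticCurve, predicted: KineticCurve) -> float:
    """Weighted sum of squares Σ (y_obs − y_pred)²/s_q² on a shared grid."""
    if observed.kind != predicted.kind:
        raise ValueError("curves carry different quantities")
    if observed.n_p != predicted.n_p or not np.allclose(
        observed.times, predicted.times, rtol=0.0, atol=1e-9
    ):
        raise ValueError("curves are sampled on different time grids")
    s = observed.s_q
    if s is None:
        s = default_uncertainty(observed.y)
    res = (observed.y - predicted.y) / s
    return float(np.dot(res, res))


def wsos_df(chi2: float, n_p: int, n: int) -> tuple[float, bool]:
    """Goodness-of-fit χ²/(n_p − n) and its acceptability (0.1–20, incl.)."""
    if n < 1:
        raise DegreesOfFreedomError("at least one fitted parameter expected")
    if n_p <= n:
        raise DegreesOfFreedomError(
            f"no degrees of freedom: n_p={n_p} points, n={n} parameters"
        )
    value = chi2 / (n_p - n)
    return value, (WSOS_DF_LOW <= value <= WSOS_DF_HIGH)


def _fraction_scale_pct(cond: ExperimentConditions) -> float:
    """Percent sorbed at equilibrium: (q_eq − q0)/(r·c0)·100."""
    if cond.c0 <= 0:
        raise ValueError("fraction fitting needs c0 > 0")
    return (cond.q_eq - cond.q0) / (cond.r * cond.c0) * 100.0


def _initial_guess(
    times: np.ndarray, y: np.ndarray, cond: ExperimentConditions, model: KineticModel
) -> float:
    """Moment-based K guess from the earliest informative point, reading
    the rise as if it were exponential (mass-transfer-like)."""
    f_eq = _fraction_scale_pct(cond)
    for t, yi in zip(times, y):
        if t > 0 and yi > 0:
            u = min(max(yi / f_eq, 1e-6), 0.999)
            kappa = -math.log1p(-u) / (cond.A * t)
            break
    else:
        kappa = 1.0 / (cond.A * max(times[-1], 1.0))
    if model in Q_DRIVEN:
        return kappa * cond.r
    return kappa * cond.Kd


def fit_overall_coefficient(
    curve: KineticCurve,
    model: KineticModel,
    cond: ExperimentConditions,
    props: SorbentProperties | None = None,
    *,
    sigma_rel: float = DEFAULT_SIGMA_REL,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR_PCT,
    epsilon: float = 1e-8,
    rtol: float = 1e-10,
) -> FitResult:
    """Fit one model's overall coefficient to an observed fraction curve.

    The distribution coefficient is taken from ``cond``; when it is None
    it is first estimated from the curve's equilibrium plateau
    (:func:`estimate_kd`).  Per-point uncertainties come from the curve,
    falling back to the max(σ_rel·y, floor) policy.

    Returns a :class:`FitResult`; ``identifiable`` is False when the
    minimizer runs into the upper search bound (a curve with no kinetic
    information, e.g. already at equilibrium at the first sample).
    """
    if curve.kind != FRACTION_PCT:
        raise ValueError("fitting expects a sorbed-fraction (%) curve")
    pos = curve.times > 0
    if int(np.count_nonzero(pos)) < 3:
        raise DegreesOfFreedomError("need at least 3 points after t = 0")
    if np.max(curve.y) <= 0:
        raise DegenerateDataError("curve carries no signal (all zero)")
    if cond.Kd is None:
        cond = ExperimentConditions(
            c0=cond.c0,
            Kd=estimate_kd(curve, cond.r),
            q0=cond.q0,
            r=cond.r,
            temperature_C=cond.temperature_C,
        )
    s_q = curve.s_q
    if s_q is None:
        s_q = default_uncertainty(curve.y, sigma_rel, sigma_floor)

    f_scale = _fraction_scale_pct(cond)
    scaled = _scaled_solution(model, cond, epsilon, rtol, 1e-12)
    times = curve.times
    yobs = curve.y
    kappa_per_K = 1.0 / cond.r if model in Q_DRIVEN else 1.0 / cond.Kd

    def predict_pct(K: float) -> np.ndarray:
        return scaled.u(K * kappa_per_K * times) * f_scale

    def objective(lgK: float) -> float:
        res = (yobs - predict_pct(10.0**lgK)) / s_q
        return float(np.dot(res, res))

    lg0 = math.log10(max(_initial_guess(times, yobs, cond, model), 1e-300))
    lo, hi = lg0 - _LOG10_BELOW, lg0 + _LOG10_ABOVE
    try:
        opt = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
    except IntegrationFailureError as exc:  # pragma: no cover - defensive
        raise FitFailureError(f"{model.value}: {exc}") from exc
    if not opt.success:
        raise FitFailureError(f"{model.value}: optimizer failed: {opt.message}")
    lg_hat = float(opt.x)
    K_hat = 10.0**lg_hat
    chi2 = float(opt.fun)
    # non-identifiable when the minimizer runs into the upper bound or the
    # objective is flat all the way up to it (no kinetic information)
    identifiable = (hi - lg_hat) > 1e-3 and objective(hi) > chi2 + 1e-6

    # 1-σ of K from the local curvature of χ² (χ² rises by 1 at K ± σ)
    def chi2_at(K: float) -> float:
        res = (yobs - predict_pct(K)) / s_q
        return float(np.dot(res, res))

    h = max(1e-4 * K_hat, 1e-300)
    curv = (chi2_at(K_hat + h) - 2.0 * chi2 + chi2_at(K_hat - h)) / (h * h)
    sigma = math.sqrt(2.0 / curv) if curv > 0 else math.nan

    n = 1
    n_p = curve.n_p
    value, acceptable = wsos_df(chi2, n_p, n)
    predicted = KineticCurve(times, predict_pct(K_hat), kind=FRACTION_PCT)
    return FitResult(
        model=model,
        K_printed=K_hat,
        sigma=sigma,
        chi2=chi2,
        wsos_df=value,
        n_p=n_p,
        n=n,
        n_d=n_p - n,
        acceptable=acceptable,
        identifiable=identifiable,
        predicted=predicted,
    )


def select_model(
    curve: KineticCurve,
    cond: ExperimentConditions,
    props: SorbentProperties | None = None,
    *,
    models: tuple[KineticModel, ...] = MODEL_ORDER,
    **fit_kwargs,
) -> tuple[list[FitResult], dict[KineticModel, Exception]]:
    """Fit every candidate model and rank by WSOS/DF (ascending).

    Ties break on the canonical model order DM < FD < ID < RLD < CR < GD.
    Individual model failures are collected, not fatal; raises only when
    every candidate fails.
    """
    results: list[FitResult] = []
    failures: dict[KineticModel, Exception] = {}
    for m in models:
        try:
            results.append(fit_overall_coefficient(curve, m, cond, props, **fit_kwargs))
        except Exception as exc:  # noqa: BLE001 - recorded per model
            failures[m] = exc
    if not results:
        raise FitFailureError(f"all candidate models failed: {failures}")
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    results.sort(key=lambda fr: (fr.wsos_df, order[fr.model]))
    return results, failures


def summarize_replicates(values) -> ReplicateSummary:
    """Mean and population σ (divide-by-N) of replicate determinations."""
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("replicate summary needs at least 2 values")
    arr = np.asarray(vals)
    return ReplicateSummary(
        values=vals, mean=float(arr.mean()), sigma_es=float(arr.std(ddof=0))
    )
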