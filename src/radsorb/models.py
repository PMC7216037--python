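"""Two-phase sorption rate laws, their closures, and time integration.

Six first-order ODE models, each naming a different rate-controlling
process, describe the transfer of a trace component from a well-stirred
aqueous phase (concentration ``c``, mol/L) into a solid sorbent
(loading ``q``, mol/kg):

========================  ====  ===========================================
control process           id    dq/dt
========================  ====  ===========================================
mass transfer             DM    K·(q* − q)
film diffusion            FD    K·(c − c*)
diffusion, inert layer    ID    K·(c − c*) / {[1 − q/q*]^(−1/3) − 1}
diffusion, reacted layer  RLD   K·(q* − q) / {[1 − q/q*]^(−1/3) − 1}
chemical reaction         CR    K′·(c − c*)·[1 − q/q*]^(2/3)
gel diffusion             GD    K·[(q* − q0)² − (q − q0)²]/(q − q0)
========================  ====  ===========================================

They are closed by the two-phase mass balance ``c = c0 − (q − q0)/r``
(``r`` the aqueous-to-solid phase ratio, L/kg) and the linear sorption
isotherm ``q* = Kd·c``, ``c* = q/Kd``.  Under these closures every driving
force collapses onto the distance to the common equilibrium loading::

    q* − q = (1 + Kd/r)·(q_eq − q),      q_eq = Kd·(c0 + q0/r)/(1 + Kd/r)

so each model is a one-parameter family in its overall coefficient.

Units
-----
Overall coefficients are reported externally in cm³·g⁻¹·min⁻¹
(≡ L·kg⁻¹·min⁻¹).  Internally the q-driven models (DM, RLD, GD) need a
per-minute coefficient, κ = K/r; the c-driven models (FD, ID, CR) use
K directly, and the reduced dimensionless ODE absorbs a further 1/Kd.
See :func:`effective_rate_constant`.

The RLD/ID/GD rate laws diverge at zero loading (integrable, q ~ √t
start-up); integration therefore starts from a small dimensionless
offset ``epsilon`` (default 1e-8) in ``u = (q − q0)/(q_eq − q0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

from .curve import FRACTION_PCT, KineticCurve
from .errors import (
    IntegrationFailureError,
    MissingParameterError,
    NoDiffusivityRelationError,
    SingularRateError,
)

__all__ = [
    "KineticModel",
    "MODEL_ORDER",
    "Q_DRIVEN",
    "C_DRIVEN",
    "ExperimentConditions",
    "SorbentProperties",
    "RateCoefficient",
    "EquilibriumState",
    "DerivedQuantities",
    "Trajectory",
    "equilibrium_state",
    "effective_rate_constant",
    "rate",
    "integrate",
    "sorption_half_life",
    "coefficient_to_diffusivity",
    "diffusivity_to_coefficient",
]

_EPS_Z = 1e-15  # floor for the shrinking-core layer factor |1 - q/q*|
_U_DONE = 1.0 - 1e-12  # dimensionless loading treated as "at equilibrium"
# models whose rate diverges at zero net loading (integrable, u ~ √τ)
_SINGULAR_AT_START = frozenset({"RLD", "ID", "GD"})


class KineticModel(str, Enum):
    """Identifier of the rate-controlling process."""

    DM = "DM"  # mass transfer
    FD = "FD"  # film diffusion
    ID = "ID"  # diffusion in an inert layer
    RLD = "RLD"  # diffusion in a reacted layer
    CR = "CR"  # chemical reaction in the reaction zone
    GD = "GD"  # gel diffusion


MODEL_ORDER = (
    KineticModel.DM,
    KineticModel.FD,
    KineticModel.ID,
    KineticModel.RLD,
    KineticModel.CR,
    KineticModel.GD,
)

#: models whose driving force is written in sorbent-phase units (q* − q)
Q_DRIVEN = frozenset({KineticModel.DM, KineticModel.RLD, KineticModel.GD})
#: models whose driving force is written in aqueous-phase units (c − c*)
C_DRIVEN = frozenset({KineticModel.FD, KineticModel.ID, KineticModel.CR})


@dataclass(frozen=True)
class ExperimentConditions:
    """Batch two-phase system at fixed phase ratio.

    Parameters
    ----------
    c0 : float
        Initial aqueous concentration, mol/L.
    Kd : float or None
        Distribution coefficient, L/kg.  May be None when it is to be
        estimated from the equilibrium plateau of a measured curve.
    q0 : float
        Initial sorbent loading, mol/kg (0 for a fresh sorbent).
    r : float
        Aqueous-to-solid phase ratio, L/kg.
    temperature_C : float
        Informational only.
    """

    c0: float
    Kd: float | None
    q0: float = 0.0
    r: float = 1000.0
    temperature_C: float = 22.0

    def __post_init__(self):
        if self.c0 < 0 or self.q0 < 0:
            raise ValueError("c0 and q0 must be nonnegative")
        if self.r <= 0:
            raise ValueError("phase ratio r must be positive")
        if self.Kd is not None and not (0 <= self.Kd < math.inf):
            raise ValueError("Kd must be finite and nonnegative")

    def _require_kd(self) -> float:
        if self.Kd is None:
            raise MissingParameterError("Kd is not set on these conditions")
        return self.Kd

    @property
    def total(self) -> float:
        """Conserved total c0 + q0/r, mol/L (aqueous-equivalent)."""
        return self.c0 + self.q0 / self.r

    @property
    def q_eq(self) -> float:
        """Equilibrium sorbent loading, mol/kg."""
        kd = self._require_kd()
        return kd * self.total / (1.0 + kd / self.r)

    @property
    def c_eq(self) -> float:
        """Equilibrium aqueous concentration, mol/L."""
        return self.total - self.q_eq / self.r

    @property
    def A(self) -> float:
        """Driving-force amplification 1 + Kd/r (dimensionless)."""
        return 1.0 + self._require_kd() / self.r


@dataclass(frozen=True)
class SorbentProperties:
    """Geometric and material constants of a nanoparticle sorbent.

    ``R_eff_cm`` is the length scale substituted for R in the
    coefficient–diffusivity relations; by convention it is the equivalent
    diameter in cm (see :func:`coefficient_to_diffusivity`).
    ``specific_mass_range`` is the (low, high) density bracket in g/cm³;
    the midpoint is the default working value.
    """

    name: str
    specific_surface_area: float  # m²/kg as reported
    equivalent_diameter_nm: float
    R_eff_cm: float
    specific_mass_range: tuple[float, float]
    film_thickness_delta_cm: float | None = None

    def __post_init__(self):
        lo, hi = self.specific_mass_range
        if self.R_eff_cm <= 0 or self.equivalent_diameter_nm <= 0:
            raise ValueError("length scales must be positive")
        if not (0 < lo <= hi):
            raise ValueError("specific mass range must satisfy 0 < low <= high")
        if self.film_thickness_delta_cm is not None and self.film_thickness_delta_cm <= 0:
            raise ValueError("film thickness must be positive")

    @property
    def h_s_mid(self) -> float:
        """Midpoint of the specific-mass range, g/cm³ (default h_s)."""
        lo, hi = self.specific_mass_range
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class RateCoefficient:
    """Overall kinetic coefficient of one model.

    ``K_printed`` carries the external reporting unit cm³·g⁻¹·min⁻¹ for
    every model; the per-minute internal coefficient depends on the
    driving-force class (see :func:`effective_rate_constant`).
    For the chemical-reaction model this is the identifiable composite
    K′ = K_CR·k_CR.
    """

    model: KineticModel
    K_printed: float

    def __post_init__(self):
        if self.K_printed < 0:
            raise ValueError("K_printed must be nonnegative")

    def kappa(self, cond: ExperimentConditions) -> float:
        """Internal coefficient: K/r (min⁻¹) for q-driven models,
        K (L·kg⁻¹·min⁻¹) for c-driven models."""
        if self.model in Q_DRIVEN:
            return self.K_printed / cond.r
        return self.K_printed


@dataclass(frozen=True)
class EquilibriumState:
    """Fixed point of the balance + isotherm system."""

    c_eq: float
    q_eq: float
    fraction_sorbed: float


@dataclass(frozen=True)
class DerivedQuantities:
    """Physical quantities derived from a fitted overall coefficient."""

    D: float | None  # cm²/min, None when the model has no D-relation
    t_half: float  # min
    fraction_sorbed_eq: float


@dataclass(frozen=True)
class Trajectory:
    """Integrated model trajectory on a sampling grid.

    ``c + q/r`` equals the conserved total at every point by construction
    (the aqueous concentration is eliminated through the mass balance).
    """

    times: np.ndarray  # min
    q: np.ndarray  # mol/kg
    c: np.ndarray  # mol/L
    cond: ExperimentConditions

    @property
    def fraction_pct(self) -> np.ndarray:
        """Sorbed fraction in percent, (q − q0)/(r·c0)·100."""
        if self.cond.c0 <= 0:
            raise ValueError("fraction undefined for c0 = 0")
        return (self.q - self.cond.q0) / (self.cond.r * self.cond.c0) * 100.0

    def as_curve(self) -> KineticCurve:
        return KineticCurve(self.times, self.fraction_pct, kind=FRACTION_PCT)


def equilibrium_state(cond: ExperimentConditions) -> EquilibriumState:
    """Solve the balance + isotherm system for its unique fixed point.

    With a fresh sorbent (q0 = 0) the sorbed fraction reduces to the
    closed form Kd/(Kd + r).
    """
    kd = cond._require_kd()
    q_eq = cond.q_eq
    c_eq = cond.c_eq
    if cond.total > 0:
        frac = (q_eq / cond.r) / cond.total
    else:
        frac = 0.0
    # Kd = 0 sorbs nothing beyond what is already on the solid
    if kd == 0:
        frac = 0.0 if cond.q0 == 0 else frac
    return EquilibriumState(c_eq=c_eq, q_eq=q_eq, fraction_sorbed=frac)


def effective_rate_constant(coeff: RateCoefficient, cond: ExperimentConditions) -> float:
    """Per-minute rate constant of the reduced dimensionless ODE.

    The reduced equation du/dτ = Φ(u) uses τ = κ_eff·t with
    κ_eff = K/r for q-driven models and κ_eff = K/Kd for c-driven ones
    (the isotherm converts c − c* to (q* − q)/Kd).
    """
    if coeff.model in Q_DRIVEN:
        return coeff.K_printed / cond.r
    kd = cond._require_kd()
    if kd <= 0:
        raise MissingParameterError("c-driven models require Kd > 0")
    return coeff.K_printed / kd


def _layer_factor(q: float, qstar: float) -> float:
    """Shrinking-core shell term 1 − q/q*, clamped below at a tiny floor
    so desorption states (q > q*) keep a defined, vanishing shell factor;
    the rate's sign is carried by the driving-force term."""
    if qstar <= 0:
        return _EPS_Z
    return max(1.0 - q / qstar, _EPS_Z)


def rate(
    model: KineticModel,
    q: float,
    cond: ExperimentConditions,
    coeff: RateCoefficient,
) -> float:
    """Pointwise dq/dt (mol·kg⁻¹·min⁻¹) of one model at loading ``q``.

    The closures eliminate c, c* and q*; the sign follows the distance to
    equilibrium, so desorption (q > q_eq) gives a negative rate.

    Raises
    ------
    SingularRateError
        At the integrable start-up singularity (RLD/ID at q = 0 with a
        fully unreacted particle, GD at q = q0).
    """
    if coeff.model is not model:
        raise ValueError("coefficient was fitted for a different model")
    if q < 0:
        raise ValueError("loading q must be nonnegative")
    kd = cond._require_kd()
    A = cond.A
    q_eq = cond.q_eq
    qstar = q + A * (q_eq - q)

    if model is KineticModel.DM:
        return (coeff.K_printed / cond.r) * (qstar - q)
    if model is KineticModel.FD:
        if kd <= 0:
            raise MissingParameterError("film diffusion requires Kd > 0")
        return coeff.K_printed * (qstar - q) / kd
    if model is KineticModel.GD:
        if q == cond.q0:
            raise SingularRateError("gel-diffusion rate diverges at q = q0")
        kq = coeff.K_printed / cond.r
        # the bracket presumes q* >= q0; clamp so desorption keeps the sign
        s = max(qstar - cond.q0, 0.0)
        return kq * (s * s - (q - cond.q0) ** 2) / (q - cond.q0)

    z = _layer_factor(q, qstar)
    if model is KineticModel.CR:
        if kd <= 0:
            raise MissingParameterError("chemical-reaction model requires Kd > 0")
        return coeff.K_printed * (qstar - q) / kd * z ** (2.0 / 3.0)
    # ID / RLD: diverge when the reacted/inert shell has zero thickness
    g = z ** (-1.0 / 3.0) - 1.0
    if g <= 0:
        raise SingularRateError(f"{model.value} rate diverges at zero shell thickness")
    if model is KineticModel.ID:
        if kd <= 0:
            raise MissingParameterError("inert-layer model requires Kd > 0")
        return coeff.K_printed * (qstar - q) / kd / g
    if model is KineticModel.RLD:
        return (coeff.K_printed / cond.r) * (qstar - q) / g
    raise ValueError(f"unknown model {model!r}")


def _reduced_rhs(model: KineticModel, A: float, rho: float):
    """du/dτ of the dimensionless sorption ODE at unit rate constant.

    u = (q − q0)/(q_eq − q0), rho = q0/(q_eq − q0); all model kinetics
    share the factor A·(1 − u) except gel diffusion.
    """

    def f(_tau, y):
        u = float(y[0])
        drive = A * (1.0 - u)
        if model is KineticModel.DM or model is KineticModel.FD:
            return (drive,)
        if model is KineticModel.GD:
            if u <= 0:
                u = _EPS_Z
            s = max(u + A * (1.0 - u), 0.0)
            return ((s * s - u * u) / u,)
        den = rho + u + A * (1.0 - u)
        if den <= 0:
            z = _EPS_Z
        else:
            z = max(1.0 - (rho + u) / den, _EPS_Z)
        if model is KineticModel.CR:
            return (drive * z ** (2.0 / 3.0),)
        g = z ** (-1.0 / 3.0) - 1.0
        if g <= 0:
            g = _EPS_Z
        return (drive / g,)

    return f


class ScaledSolution:
    """Dimensionless solution u(τ) of one model/conditions pair.

    Because the reduced ODE du/dτ = Φ(u) carries no rate constant, one
    integration serves every coefficient value: u(t; K) = u(κ_eff(K)·t).
    The fitter exploits this to evaluate trial coefficients by rescaling
    time instead of re-integrating.
    """

    def __init__(
        self,
        model: KineticModel,
        cond: ExperimentConditions,
        *,
        epsilon: float = 1e-8,
        rtol: float = 1e-10,
        atol: float = 1e-12,
    ):
        self.model = model
        self.cond = cond
        self.epsilon = float(epsilon)
        if cond.q_eq <= cond.q0:
            raise ValueError("scaled solution requires q_eq > q0")
        delta = cond.q_eq - cond.q0
        rho = cond.q0 / delta
        rhs = _reduced_rhs(model, cond.A, rho)
        # only the models singular at zero loading need the ε-offset start
        u0 = self.epsilon if model.value in _SINGULAR_AT_START else 0.0

        def done(_tau, y):
            return y[0] - _U_DONE

        done.terminal = True

        def half(_tau, y):
            return y[0] - 0.5

        half.terminal = False

        tau_end = 50.0 * math.log(2.0) / cond.A  # generous for the exponential models
        for _ in range(12):
            sol = solve_ivp(
                rhs,
                (0.0, tau_end),
                [u0],
                method="LSODA",
                rtol=rtol,
                atol=atol,
                dense_output=True,
                events=(done, half),
            )
            if sol.status == -1:
                raise IntegrationFailureError(
                    f"{model.value} integration failed: {sol.message}"
                )
            if sol.t_events[0].size:
                break
            tau_end *= 20.0
        else:
            raise IntegrationFailureError(
                f"{model.value}: equilibrium not reached within τ = {tau_end:g}"
            )
        self._sol = sol
        self.tau_done = float(sol.t_events[0][0])
        self.tau_half = float(sol.t_events[1][0]) if sol.t_events[1].size else math.nan

    def u(self, tau) -> np.ndarray:
        """Dimensionless loading at reduced times ``tau`` (array)."""
        tau = np.asarray(tau, dtype=float)
        out = np.empty_like(tau)
        inside = tau < self.tau_done
        if np.any(inside):
            out[inside] = self._sol.sol(tau[inside])[0]
        out[~inside] = _U_DONE
        out[tau <= 0.0] = 0.0
        np.clip(out, 0.0, 1.0, out=out)
        # kill sub-tolerance wiggles so trajectories are exactly monotone
        return np.maximum.accumulate(out)


@lru_cache(maxsize=128)
def _scaled_solution(
    model: KineticModel,
    cond: ExperimentConditions,
    epsilon: float,
    rtol: float,
    atol: float,
) -> ScaledSolution:
    """Memoized dimensionless solution: it depends only on the model and
    the (hashable, frozen) conditions, not on the rate coefficient, so
    repeated fits and integrations under the same conditions reuse it."""
    return ScaledSolution(model, cond, epsilon=epsilon, rtol=rtol, atol=atol)


def integrate(
    model: KineticModel,
    cond: ExperimentConditions,
    coeff: RateCoefficient,
    times,
    *,
    epsilon: float = 1e-8,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate one model over a sampling grid.

    Returns a :class:`Trajectory` with q(t), and c(t) recovered from the
    mass balance (hence conserved to machine precision).  q(0) = q0
    exactly; the ε-offset start regularizes the RLD/ID/GD singularity.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be nonnegative and strictly increasing")
    q_eq = cond.q_eq
    if q_eq < cond.q0:
        raise ValueError("desorption trajectories (q0 > q_eq) are not integrated")
    if q_eq == cond.q0 or coeff.K_printed == 0:
        q = np.full_like(times, cond.q0)
    else:
        kappa = effective_rate_constant(coeff, cond)
        scaled = _scaled_solution(model, cond, epsilon, rtol, atol)
        u = scaled.u(kappa * times)
        q = cond.q0 + u * (q_eq - cond.q0)
    c = cond.c0 - (q - cond.q0) / cond.r
    return Trajectory(times=times, q=q, c=c, cond=cond)


def sorption_half_life(
    model: KineticModel,
    cond: ExperimentConditions,
    coeff: RateCoefficient,
    *,
    epsilon: float = 1e-8,
) -> float:
    """Time (min) at which the loading reaches half its equilibrium rise,
    q = q0 + (q_eq − q0)/2, on the integrated model curve."""
    if cond.q_eq <= cond.q0:
        raise ValueError("half-life undefined: q_eq must exceed q0")
    if coeff.K_printed <= 0:
        raise ValueError("half-life undefined for a zero rate coefficient")
    kappa = effective_rate_constant(coeff, cond)
    scaled = _scaled_solution(model, cond, epsilon, 1e-10, 1e-12)
    if math.isnan(scaled.tau_half):
        raise IntegrationFailureError("half-crossing not located")
    return scaled.tau_half / kappa


def coefficient_to_diffusivity(
    model: KineticModel,
    K_printed: float,
    props: SorbentProperties,
    *,
    h_s: float | None = None,
) -> float:
    """Invert a model's coefficient–diffusivity relation for D (cm²/min).

    RLD/ID: K = 3·D/(R²·h_s)   →  D = K·R²·h_s/3
    FD:     K = 3·D/(δ·R·h_s)  →  D = K·δ·R·h_s/3
    GD:     K = D·π²/(2·R²)    →  D = 2·K·R²/π²

    ``h_s`` defaults to the midpoint of the sorbent's specific-mass range.
    DM and CR have no diffusivity relation.
    """
    if K_printed < 0:
        raise ValueError("K_printed must be nonnegative")
    h = props.h_s_mid if h_s is None else h_s
    R = props.R_eff_cm
    if model in (KineticModel.RLD, KineticModel.ID):
        return K_printed * R * R * h / 3.0
    if model is KineticModel.FD:
        if props.film_thickness_delta_cm is None:
            raise MissingParameterError("film diffusion needs film_thickness_delta_cm")
        return K_printed * props.film_thickness_delta_cm * R * h / 3.0
    if model is KineticModel.GD:
        return 2.0 * K_printed * R * R / math.pi**2
    raise NoDiffusivityRelationError(
        f"{model.value} coefficient is not related to a diffusion coefficient"
    )


def diffusivity_to_coefficient(
    model: KineticModel,
    D: float,
    props: SorbentProperties,
    *,
    h_s: float | None = None,
) -> float:
    """Forward relation D → K (exact inverse of
    :func:`coefficient_to_diffusivity`)."""
    if D < 0:
        raise ValueError("D must be nonnegative")
    h = props.h_s_mid if h_s is None else h_s
    R = props.R_eff_cm
    if model in (KineticModel.RLD, KineticModel.ID):
        return 3.0 * D / (R * R * h)
    if model is KineticModel.FD:
        if props.film_thickness_delta_cm is None:
            raise MissingParameterError("film diffusion needs film_thickness_delta_cm")
        return 3.0 * D / (props.film_thickness_delta_cm * R * h)
    if model is KineticModel.GD:
        return D * math.pi**2 / (2.0 * R * R)
    raise NoDiffusivityRelationError(
        f"{model.value} coefficient is not related to a diffusion coefficient"
    )
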