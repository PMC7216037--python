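"""Activity ↔ concentration conversions and decay arithmetic for Ra-223.

A radiotracer batch experiment never measures moles directly: the
aqueous concentration follows from the absolute activity A (Bq) through
c = A·T½ / (ln2 · V_aq · N_A), and the sorbed fraction follows from the
activity split between the separated supernatant (A_s) and the
nanoparticle pellet (A_p).  Both phases of one aliquot decay
identically, so the fraction itself is decay-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "NuclideSpec",
    "RA223",
    "ActivityMeasurement",
    "activity_to_concentration",
    "concentration_to_activity",
    "sorbed_fraction_from_activities",
    "decay",
    "decay_correct",
]

AVOGADRO = 6.02214076e23  # mol⁻¹

_DAY_S = 86400.0


@dataclass(frozen=True)
class NuclideSpec:
    """A radionuclide identified by its half-life."""

    name: str
    T_half_s: float

    def __post_init__(self):
        if self.T_half_s <= 0:
            raise ValueError("half-life must be positive")


#: Radium-223, the in-vivo-generator nuclide (T½ = 11.4 d)
RA223 = NuclideSpec("Ra-223", 11.4 * _DAY_S)


@dataclass(frozen=True)
class ActivityMeasurement:
    """Supernatant/pellet activity pair from one centrifuged aliquot."""

    A_s: float  # Bq, supernatant
    A_p: float  # Bq, nanoparticles
    t_meas_min: float = 0.0

    def __post_init__(self):
        if self.A_s < 0 or self.A_p < 0:
            raise ValueError("activities must be nonnegative")


def activity_to_concentration(A: float, nuclide: NuclideSpec, V_aq_L: float) -> float:
    """Molar concentration (mol/L) of a carrier-free tracer with absolute
    activity ``A`` (Bq) in volume ``V_aq_L`` (L)."""
    if A < 0:
        raise ValueError("activity must be nonnegative")
    if V_aq_L <= 0:
        raise ValueError("aqueous volume must be positive")
    return A * nuclide.T_half_s / (math.log(2.0) * V_aq_L * AVOGADRO)


def concentration_to_activity(c: float, nuclide: NuclideSpec, V_aq_L: float) -> float:
    """Inverse of :func:`activity_to_concentration` (Bq)."""
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    if V_aq_L <= 0:
        raise ValueError("aqueous volume must be positive")
    return c * math.log(2.0) * V_aq_L * AVOGADRO / nuclide.T_half_s


def sorbed_fraction_from_activities(
    m: ActivityMeasurement, *, supernatant_form: bool = False
) -> float:
    """Radiochemical yield Y (%) of tracer bound to the solid phase.

    Default is the adsorbed-fraction form A_p/(A_s + A_p)·100, which is
    the quantity the kinetic models predict.  ``supernatant_form=True``
    returns A_s/(A_s + A_p)·100 instead (the complementary split,
    sometimes quoted when the supernatant is the measured phase).
    """
    total = m.A_s + m.A_p
    if total <= 0:
        raise ValueError("total activity must be positive")
    num = m.A_s if supernatant_form else m.A_p
    return num / total * 100.0


def decay(A: float, dt_s: float, nuclide: NuclideSpec) -> float:
    """Activity after elapsing ``dt_s`` seconds: A·2^(−dt/T½)."""
    return A * 2.0 ** (-dt_s / nuclide.T_half_s)


def decay_correct(A: float, dt_s: float, nuclide: NuclideSpec) -> float:
    """Back-correct a measured activity to ``dt_s`` seconds earlier:
    A0 = A·2^(dt/T½).  Exact inverse of :func:`decay`."""
    if dt_s < 0:
        raise ValueError("dt must be nonnegative")
    return A * 2.0 ** (dt_s / nuclide.T_half_s)
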