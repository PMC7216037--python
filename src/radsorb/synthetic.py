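"""Virtual batch radiotracer sorption experiments.

Emulates the laboratory protocol behind the reference data: a 24-h
batch contact at 1 g/L sorbent (r = 1000 L/kg) and tracer-level initial
concentration (~1e-11 mol/L), sampled by 0.5-mL aliquots on a fixed
25-point schedule (dense over the first hour, sparse to 24 h), with the
sorbed fraction measured from the supernatant/pellet activity split of
each centrifuged aliquot.

Two noise modes:

* Gaussian (default): additive noise with sd max(σ_rel·f, floor) on the
  percent-sorbed value, clamped to [0, 100] — a lumped model of the
  counting and handling error.
* Poisson: simulated supernatant/pellet counts at a configurable
  expected total per aliquot, routed through the same activity-split
  formula the laboratory uses; optionally decayed over the elapsed time
  (which must, and does, leave the fraction unchanged).

The per-point ``s_q`` written into the observed curve is the sd the
noise model actually used, so a fit with these uncertainties is
correctly specified by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curve import FRACTION_PCT, KineticCurve
from .inference import DEFAULT_SIGMA_FLOOR_PCT, DEFAULT_SIGMA_REL
from .models import ExperimentConditions, KineticModel, RateCoefficient, integrate
from .radioactivity import RA223, ActivityMeasurement, NuclideSpec, decay, sorbed_fraction_from_activities

__all__ = ["ProtocolConfig", "default_schedule", "generate_experiment"]


def default_schedule() -> np.ndarray:
    """The 25-point aliquot schedule (min): an immediate zero aliquot,
    every minute to 10 min, then 15–60 min, then 2–24 h."""
    return np.array(
        [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 25, 30, 40, 50, 60,
         120, 180, 240, 300, 420, 600, 1440],
        dtype=float,
    )


@dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of one virtual experiment.

    ``counts_per_sample`` switches to Poisson counting noise (expected
    total counts per aliquot); otherwise Gaussian noise with relative sd
    ``sigma_rel`` and absolute floor ``noise_floor_pct`` applies.
    """

    cond: ExperimentConditions
    truth_model: KineticModel
    truth_K_printed: float
    schedule: np.ndarray = field(default_factory=default_schedule)
    sigma_rel: float = DEFAULT_SIGMA_REL
    noise_floor_pct: float = DEFAULT_SIGMA_FLOOR_PCT
    counts_per_sample: float | None = None
    seed: int = 0
    decay: bool = False
    nuclide: NuclideSpec = RA223
    epsilon: float = 1e-8

    def __post_init__(self):
        sched = np.asarray(self.schedule, dtype=float)
        object.__setattr__(self, "schedule", sched)
        if sched.ndim != 1 or np.any(np.diff(sched) <= 0) or sched[0] < 0:
            raise ValueError("schedule must be nonnegative, strictly increasing")
        if self.sigma_rel < 0 or self.noise_floor_pct < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.counts_per_sample is not None and self.counts_per_sample <= 0:
            raise ValueError("counts_per_sample must be positive")
        if self.truth_K_printed < 0:
            raise ValueError("truth_K_printed must be nonnegative")


def _gaussian_observe(truth_pct, cfg, rng):
    sd = np.maximum(cfg.sigma_rel * truth_pct, cfg.noise_floor_pct)
    obs = np.clip(truth_pct + rng.normal(0.0, 1.0, truth_pct.size) * sd, 0.0, 100.0)
    return obs, sd


def _poisson_observe(truth_pct, times, cfg, rng):
    p = truth_pct / 100.0
    lam_total = np.full_like(p, float(cfg.counts_per_sample))
    if cfg.decay:
        # both phases of an aliquot decay identically; the expected
        # fraction is decay-invariant, only the counting statistics soften
        lam_total = np.array(
            [decay(lt, t * 60.0, cfg.nuclide) for lt, t in zip(lam_total, times)]
        )
    counts_p = rng.poisson(lam_total * p)
    counts_s = rng.poisson(lam_total * (1.0 - p))
    obs = np.empty_like(p)
    for i, (cs, cp) in enumerate(zip(counts_s, counts_p)):
        if cs + cp == 0:
            obs[i] = truth_pct[i]  # dead aliquot carries no information
        else:
            obs[i] = sorbed_fraction_from_activities(
                ActivityMeasurement(A_s=float(cs), A_p=float(cp))
            )
    # binomial sd of the fraction estimate at the expected counts
    sd = 100.0 * np.sqrt(np.maximum(p * (1.0 - p), 1e-12) / lam_total)
    return obs, np.maximum(sd, 1e-6)


def generate_experiment(cfg: ProtocolConfig) -> tuple[KineticCurve, KineticCurve]:
    """Simulate one experiment; returns (observed, truth) curves.

    The truth curve is the noiseless integrated model sampled on the
    schedule; the observed curve perturbs it with the configured noise
    and carries the matching per-point ``s_q``.  Identical seeds give
    identical output.
    """
    coeff = RateCoefficient(cfg.truth_model, cfg.truth_K_printed)
    traj = integrate(
        cfg.truth_model, cfg.cond, coeff, cfg.schedule, epsilon=cfg.epsilon
    )
    truth_pct = traj.fraction_pct
    truth = KineticCurve(cfg.schedule, truth_pct, kind=FRACTION_PCT)

    rng = np.random.default_rng(cfg.seed)
    if cfg.counts_per_sample is not None:
        obs, sd = _poisson_observe(truth_pct, cfg.schedule, cfg, rng)
    elif cfg.sigma_rel == 0:
        obs, sd = truth_pct.copy(), None  # noise switched off entirely
    else:
        obs, sd = _gaussian_observe(truth_pct, cfg, rng)
    observed = KineticCurve(cfg.schedule, obs, s_q=sd, kind=FRACTION_PCT)
    return observed, truth
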