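"""Exception hierarchy for radsorb."""


class RadsorbError(Exception):
    """Base class for all radsorb errors."""


class SingularRateError(RadsorbError):
    """Rate law evaluated exactly at an integrable singularity (e.g. zero
    loading for the reacted-layer or gel-diffusion models); use the
    regularized integrator instead of the pointwise rate."""


class IntegrationFailureError(RadsorbError):
    """The ODE solver did not converge; carries the solver diagnostic."""


class NoDiffusivityRelationError(RadsorbError):
    """The model's overall coefficient has no relation to a diffusion
    coefficient (mass transfer, chemical reaction)."""


class MissingParameterError(RadsorbError):
    """A required physical parameter (e.g. film thickness for the film
    diffusion model) was not provided."""


class DegreesOfFreedomError(RadsorbError):
    """Fewer data points than fitted parameters plus one."""


class DegenerateDataError(RadsorbError):
    """The observed curve carries no usable signal (e.g. all zero)."""


class FitFailureError(RadsorbError):
    """Coefficient fit did not converge; ``best`` holds the best-so-far
    result if one exists."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
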