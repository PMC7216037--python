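"""Kinetic-curve container shared by the model and inference layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: observed/predicted quantity kinds
FRACTION_PCT = "fraction_pct"
CONCENTRATION = "conc_mol_per_L"


@dataclass(frozen=True)
class KineticCurve:
    """A sampled sorption kinetic curve.

    Parameters
    ----------
    times : array-like
        Sampling times in minutes, strictly increasing; t = 0 allowed.
    y : array-like
        Observed (or predicted) values: sorbed fraction in percent when
        ``kind == "fraction_pct"``, aqueous concentration in mol/L when
        ``kind == "conc_mol_per_L"``.
    s_q : array-like, optional
        Per-point standard-deviation estimates in the same units as ``y``.
        Must be strictly positive when given.
    kind : str
        One of :data:`FRACTION_PCT`, :data:`CONCENTRATION`.
    """

    times: np.ndarray
    y: np.ndarray
    s_q: np.ndarray | None = None
    kind: str = FRACTION_PCT

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and y must be 1-D arrays of equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if self.s_q is not None:
            s = np.asarray(self.s_q, dtype=float)
            if s.shape != t.shape:
                raise ValueError("s_q must match times in length")
            if np.any(s <= 0):
                raise ValueError("s_q must be strictly positive")
            object.__setattr__(self, "s_q", s)
        if self.kind not in (FRACTION_PCT, CONCENTRATION):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    @property
    def n_p(self) -> int:
        """Number of experimental points."""
        return int(self.times.size)
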