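"""Angle-trace container shared by the movie generator and the angular
statistics layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import wrap360

__all__ = ["AngleTrace"]


@dataclass
class AngleTrace:
    """Uniformly sampled angular trajectory of one particle.

    ``theta`` is the unwrapped (cumulative) angle in degrees; the wrapped
    representation in [0, 360) is available as :attr:`theta_wrapped`.
    Angles follow the image convention: measured from +x (columns) towards
    +y (rows, increasing downward).
    """

    times: np.ndarray
    theta: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.times.shape != self.theta.shape:
            raise ValueError("times and theta must have matching shapes")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-12):
                raise ValueError("trace must be uniformly sampled at dt")

    @property
    def theta_wrapped(self) -> np.ndarray:
        return wrap360(self.theta)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) else 0.0

    def __len__(self) -> int:
        return len(self.times)
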