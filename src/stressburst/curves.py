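"""Time-varying rate curves used by scenario configurations.

All curves are functions of time in minutes *relative to treatment onset*
(negative = before treatment). Each curve knows how to evaluate itself at
arbitrary times and how to integrate itself exactly over an interval, which
is what the inhomogeneous-Poisson event sampler and the survival model need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.355


@dataclass(frozen=True)
class PiecewiseLinearCurve:
    """Piecewise-linear curve defined by (time, value) knots.

    Values are held constant beyond the first/last knot. Integration is
    exact (trapezoid on the knot grid).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 1:
            raise ValueError("knots must be matching 1-D arrays with >= 1 point")
        if np.any(np.diff(t) < 0):
            raise ValueError("knot times must be nondecreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_knots(cls, knots) -> "PiecewiseLinearCurve":
        arr = np.asarray(knots, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("knots must be a sequence of (time, value) pairs")
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def constant(cls, value: float) -> "PiecewiseLinearCurve":
        return cls(np.array([0.0]), np.array([float(value)]))

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)

    def integral(self, t0: float, t1: float) -> float:
        """Exact integral of the curve over [t0, t1]."""
        if t1 < t0:
            return -self.integral(t1, t0)
        # evaluate on the union of interval ends and interior knots
        interior = self.times[(self.times > t0) & (self.times < t1)]
        grid = np.concatenate(([t0], interior, [t1]))
        vals = self(grid)
        return float(np.trapezoid(vals, grid))

    @property
    def min_value(self) -> float:
        return float(np.min(self.values))


@dataclass(frozen=True)
class GaussianBurstCurve:
    """Baseline plus a Gaussian burst: b + (p − b)·exp(−(t − t_peak)²/2σ²).

    Parameters are the summary quantities an experimenter would report for
    a transient burst: baseline level, peak level, peak time and full width
    at half maximum (σ = fwhm / 2.355).
    """

    baseline: float
    peak: float
    t_peak: float
    fwhm: float

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_TO_SIGMA

    @property
    def amplitude(self) -> float:
        return self.peak - self.baseline

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.fwhm == 0 or self.amplitude == 0:
            return np.full_like(t, self.baseline, dtype=float)
        z = (t - self.t_peak) / self.sigma
        return self.baseline + self.amplitude * np.exp(-0.5 * z * z)

    def integral(self, t0: float, t1: float) -> float:
        base = self.baseline * (t1 - t0)
        if self.fwhm == 0 or self.amplitude == 0:
            return base
        s = self.sigma
        z0 = (t0 - self.t_peak) / (s * np.sqrt(2.0))
        z1 = (t1 - self.t_peak) / (s * np.sqrt(2.0))
        burst = self.amplitude * s * np.sqrt(np.pi / 2.0) * (erf(z1) - erf(z0))
        return float(base + burst)

    @property
    def min_value(self) -> float:
        return float(min(self.baseline, self.peak))


@dataclass(frozen=True)
class BoundProbCurve:
    """Bound probability vs time for the two-state tracking model.

    Basal level before treatment, linear rise to the peak at ``t_peak``
    (the earliest post-treatment observation), then exponential relaxation
    back toward basal with half-life ``t_half``.
    """

    basal: float
    peak: float
    t_peak: float
    t_half: float

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.basal, dtype=float)
        rising = (t > 0) & (t < self.t_peak)
        if self.t_peak > 0:
            out[rising] = self.basal + (self.peak - self.basal) * t[rising] / self.t_peak
        decaying = t >= self.t_peak
        out[decaying] = self.basal + (self.peak - self.basal) * np.exp2(
            -(t[decaying] - self.t_peak) / self.t_half
        )
        return out

    @property
    def min_value(self) -> float:
        return float(min(self.basal, self.peak))
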