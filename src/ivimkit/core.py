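"""Bi-exponential diffusion signal model and the segmented two-step fit.

The signal from a voxel containing a perfusing capillary compartment on top
of ordinary tissue water is modelled as

    S(b) = S0 * ((1 - f) * exp(-b * D) + f * exp(-b * Dp))

with tissue diffusion coefficient ``D`` (mm^2/s), perfusion fraction ``f``
and pseudo-diffusion coefficient ``Dp >= D``.  Above a threshold b-value the
perfusion term is negligible and the decay is mono-exponential with
intercept ``S0 * (1 - f)``, which is what the segmented fit exploits:

1. ordinary least squares on ``log(S)`` over the high-b points gives ``D``
   (negative slope) and ``f`` (from the intercept against the measured b=0
   signal);
2. with ``D`` and ``f`` held fixed, a bounded one-parameter least-squares
   fit of the full bi-exponential over *all* b-values gives ``Dp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DEFAULT_B_VALUES",
    "DEFAULT_AVERAGES",
    "BValueScheme",
    "SignalCurve",
    "IvimParams",
    "FitConfig",
    "FitError",
    "ivim_signal",
    "high_b_signal",
    "fit_adc_two_point",
    "segmented_fit",
]

#: 10-point knee protocol: b-values in s/mm^2 and signal averages (NEX) per b.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 600.0, 800.0, 1000.0)
DEFAULT_AVERAGES = (1, 1, 1, 1, 1, 1, 2, 2, 3, 3)


class FitError(RuntimeError):
    """A signal curve could not be fitted (too few usable points, bad data)."""


@dataclass(frozen=True)
class BValueScheme:
    """Acquisition scheme: ascending b-values starting at 0, with NEX counts."""

    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    averages: tuple[int, ...] = DEFAULT_AVERAGES

    def __post_init__(self) -> None:
        b = tuple(float(v) for v in self.b_values)
        a = tuple(int(v) for v in self.averages)
        if len(b) != len(a):
            raise ValueError("b_values and averages must have equal length")
        if len(b) == 0:
            raise ValueError("scheme must contain at least one b-value")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("b-values must be strictly increasing")
        if any(n < 1 for n in a):
            raise ValueError("averages must be positive integers")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "averages", a)

    def __len__(self) -> int:
        return len(self.b_values)

    def high_b_mask(self, b_threshold: float) -> np.ndarray:
        """Boolean mask of b-values at or above the threshold (inclusive)."""
        return np.asarray(self.b_values) >= b_threshold

    def index_of(self, b: float) -> int:
        try:
            return self.b_values.index(float(b))
        except ValueError as exc:
            raise KeyError(f"b={b} not in scheme") from exc


@dataclass(frozen=True)
class SignalCurve:
    """One voxel's (or ROI's) signal intensities, one per scheme b-value."""

    scheme: BValueScheme
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        sig = tuple(float(v) for v in self.signal)
        if len(sig) != len(self.scheme):
            raise ValueError("signal length must match scheme length")
        if any(v < 0 for v in sig):
            raise ValueError("signal intensities must be non-negative")
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class IvimParams:
    """Bi-exponential model parameters for one voxel or tissue."""

    S0: float
    D: float
    f: float
    Dp: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError("S0 must be non-negative")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.Dp < self.D:
            raise ValueError("Dp must be >= D")


@dataclass(frozen=True)
class FitConfig:
    """Deterministic settings for the segmented fit.

    ``b_threshold`` is inclusive: the point at exactly the threshold belongs
    to the high-b (mono-exponential) set.
    """

    b_threshold: float = 200.0
    d_min: float = 1e-5
    d_max: float = 4e-3
    f_min: float = 0.0
    f_max: float = 1.0
    dp_max: float = 0.5
    dp_init_factor: float = 10.0
    dp_xatol: float = 1e-12
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.b_threshold < 0:
            raise ValueError("b_threshold must be non-negative")
        if not 0 < self.d_min < self.d_max:
            raise ValueError("require 0 < d_min < d_max")
        if not 0.0 <= self.f_min < self.f_max <= 1.0:
            raise ValueError("require 0 <= f_min < f_max <= 1")
        if self.dp_max <= self.d_max:
            raise ValueError("dp_max must exceed d_max")

    def to_dict(self) -> dict:
        return {
            "b_threshold": self.b_threshold,
            "d_min": self.d_min,
            "d_max": self.d_max,
            "f_min": self.f_min,
            "f_max": self.f_max,
            "dp_max": self.dp_max,
            "dp_init_factor": self.dp_init_factor,
            "dp_xatol": self.dp_xatol,
            "max_iter": self.max_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        return cls(**d)


def _validate_b(b) -> np.ndarray:
    arr = np.asarray(b, dtype=float)
    if np.any(arr < 0):
        raise ValueError("b-values must be non-negative")
    return arr


def ivim_signal(p: IvimParams, b) -> np.ndarray | float:
    """Evaluate the bi-exponential model at one or many b-values."""
    arr = _validate_b(b)
    out = p.S0 * ((1.0 - p.f) * np.exp(-arr * p.D) + p.f * np.exp(-arr * p.Dp))
    return out if arr.ndim else float(out)


def high_b_signal(p: IvimParams, b) -> np.ndarray | float:
    """Mono-exponential limb valid above the threshold: S0*(1-f)*exp(-b*D)."""
    arr = _validate_b(b)
    out = p.S0 * (1.0 - p.f) * np.exp(-arr * p.D)
    return out if arr.ndim else float(out)


def fit_adc_two_point(s0: float, s1000: float, b_high: float = 1000.0) -> float:
    """Two-point mono-exponential ADC over b = 0 and b = b_high.

    Returns NaN (undefined-voxel marker) for non-positive inputs rather than
    raising, so map code can call it wholesale.
    """
    if s0 <= 0 or s1000 <= 0 or not (math.isfinite(s0) and math.isfinite(s1000)):
        return float("nan")
    return math.log(s0 / s1000) / b_high


def _step1_log_linear(
    b: np.ndarray, s: np.ndarray, cfg: FitConfig
) -> tuple[float, float, bool]:
    """High-b log-linear stage.  Returns (D, f, clamped)."""
    hi = b >= cfg.b_threshold
    if int(hi.sum()) < 3:
        raise FitError("fewer than 3 b-values at/above the threshold")
    s_hi = s[hi]
    if np.any(s_hi <= 0) or s[0] <= 0:
        raise FitError("non-positive signal in log-linear stage")
    slope, intercept = np.polyfit(b[hi], np.log(s_hi), 1)
    clamped = False
    d = -float(slope)
    if not cfg.d_min <= d <= cfg.d_max:
        d = min(max(d, cfg.d_min), cfg.d_max)
        clamped = True
    f = 1.0 - math.exp(float(intercept)) / s[0]
    if not cfg.f_min <= f <= cfg.f_max:
        f = min(max(f, cfg.f_min), cfg.f_max)
        clamped = True
    return d, f, clamped


def segmented_fit(curve: SignalCurve, cfg: FitConfig | None = None) -> IvimParams:
    """Two-step segmented fit of one signal curve.

    Raises :class:`FitError` when the log-linear stage is unusable (fewer
    than 3 high-b points, or non-positive signal).  Out-of-range step-1
    estimates are clamped to the configured bounds.
    """
    cfg = cfg or FitConfig()
    b = np.asarray(curve.scheme.b_values, dtype=float)
    s = np.asarray(curve.signal, dtype=float)
    d, f, _ = _step1_log_linear(b, s, cfg)

    s0 = float(s[0])
    dp0 = min(cfg.dp_init_factor * d, cfg.dp_max)
    if f == 0.0:
        # Dp unidentifiable; keep the conventional initial value.
        return IvimParams(S0=s0, D=d, f=f, Dp=dp0)

    diffusive = s0 * (1.0 - f) * np.exp(-b * d)

    def sse(dp: float) -> float:
        resid = diffusive + s0 * f * np.exp(-b * dp) - s
        return float(resid @ resid)

    res = minimize_scalar(
        sse,
        bounds=(d, cfg.dp_max),
        method="bounded",
        options={"xatol": cfg.dp_xatol, "maxiter": cfg.max_iter},
    )
    dp = float(min(max(res.x, d), cfg.dp_max))
    return IvimParams(S0=s0, D=d, f=f, Dp=dp)
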