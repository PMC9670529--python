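"""Voxelwise parameter mapping: intensity masking and whole-volume fitting."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    BValueScheme,
    FitConfig,
    FitError,
    SignalCurve,
    fit_adc_two_point,
    segmented_fit,
)

__all__ = ["DwiSeries", "ParameterMapSet", "compute_mask", "fit_volume"]

log = logging.getLogger(__name__)

#: Fraction of the maximum b=0 intensity below which voxels are masked out.
DEFAULT_MASK_FRACTION = 0.30


@dataclass
class DwiSeries:
    """A multi-b-value DWI acquisition: last axis indexes the b-value."""

    scheme: BValueScheme
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.3, 1.3, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            raise ValueError("data must have at least one spatial axis plus the b axis")
        if self.data.shape[-1] != len(self.scheme):
            raise ValueError(
                f"data has {self.data.shape[-1]} b-volumes, scheme has {len(self.scheme)}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def b0(self) -> np.ndarray:
        return self.data[..., 0]

    def volume(self, b: float) -> np.ndarray:
        return self.data[..., self.scheme.index_of(b)]


@dataclass
class ParameterMapSet:
    """Masked voxelwise maps in internal units (mm^2/s, fraction)."""

    D: np.ndarray
    f: np.ndarray
    Dp: np.ndarray
    adc: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.D, self.f, self.Dp, self.adc, self.mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one spatial shape")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


def compute_mask(b0_volume: np.ndarray, fraction: float = DEFAULT_MASK_FRACTION) -> np.ndarray:
    """Voxels with b=0 intensity strictly below ``fraction`` of the volume-wide
    maximum are masked out; a voxel at exactly the cutoff stays in."""
    vol = np.asarray(b0_volume, dtype=float)
    if vol.size == 0:
        raise ValueError("empty b0 volume")
    vmax = float(vol.max())
    if vmax <= 0:
        raise ValueError("b0 volume has no positive maximum to scale against")
    return vol >= fraction * vmax


def fit_volume(
    series: DwiSeries,
    cfg: FitConfig | None = None,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
    mask: np.ndarray | None = None,
) -> ParameterMapSet:
    """Run the segmented fit and the two-point ADC on every masked-in voxel.

    Voxels outside the mask, or whose fit fails, carry NaN in every map.
    Failures are logged with their index and never abort the volume.
    """
    cfg = cfg or FitConfig()
    if mask is None:
        mask = compute_mask(series.b0, mask_fraction)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.shape:
            raise ValueError("mask shape must match the series' spatial shape")

    shape = series.shape
    d_map = np.full(shape, np.nan)
    f_map = np.full(shape, np.nan)
    dp_map = np.full(shape, np.nan)
    adc_map = np.full(shape, np.nan)
    fitted = np.zeros(shape, dtype=bool)

    i1000 = series.scheme.index_of(1000.0) if 1000.0 in series.scheme.b_values else None

    for idx in np.argwhere(mask):
        key = tuple(idx)
        sig = series.data[key]
        try:
            p = segmented_fit(SignalCurve(series.scheme, tuple(sig)), cfg)
        except (FitError, ValueError) as exc:
            log.warning("fit failed at voxel %s: %s", key, exc)
            continue
        d_map[key] = p.D
        f_map[key] = p.f
        dp_map[key] = p.Dp
        fitted[key] = True
        if i1000 is not None:
            adc_map[key] = fit_adc_two_point(sig[0], sig[i1000])

    return ParameterMapSet(D=d_map, f=f_map, Dp=dp_map, adc=adc_map, mask=fitted)
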