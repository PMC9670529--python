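"""ROI-level quantification and nonparametric group comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.stats import mannwhitneyu

from .maps import ParameterMapSet

__all__ = [
    "EmptyRoiError",
    "SummaryStats",
    "RoiMeasurement",
    "GroupComparisonResult",
    "extract_roi_stats",
    "perturb_roi",
    "repeat_cov",
    "mann_whitney",
]


class EmptyRoiError(ValueError):
    """ROI contains no masked-in voxels."""


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    min: float
    max: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        tol = 1e-9 * max(1.0, abs(self.min), abs(self.max))  # mean of equal values can be off by 1 ulp
        if not self.min - tol <= self.mean <= self.max + tol:
            raise ValueError("require min <= mean <= max")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise EmptyRoiError("no values to summarize")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(mean=float(v.mean()), sd=sd, min=float(v.min()), max=float(v.max()), count=int(v.size))


@dataclass
class RoiMeasurement:
    """One subject x tissue quantification from the masked parameter maps."""

    subject_id: str
    tissue: str
    d: SummaryStats
    f: SummaryStats
    b1000_signal: float | None = None


def perturb_roi(roi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Seeded one-voxel boundary perturbation of a boolean ROI: each inner
    boundary voxel is dropped and each outer boundary voxel added with
    probability 1/2.  Models a second independent manual drawing."""
    roi = np.asarray(roi, dtype=bool)
    inner = roi & ~binary_erosion(roi)
    outer = binary_dilation(roi) & ~roi
    out = roi.copy()
    out[inner] = rng.random(int(inner.sum())) < 0.5
    out[outer] = rng.random(int(outer.sum())) < 0.5
    return out


def extract_roi_stats(
    maps: ParameterMapSet,
    roi: np.ndarray,
    label: int,
    *,
    subject_id: str = "",
    tissue: str = "",
    b1000_volume: np.ndarray | None = None,
    repeat_seed: int = 0,
) -> RoiMeasurement:
    """Mean/SD/min/max of D and f over the ROI's masked-in voxels.

    When the b=1000 volume is supplied, its ROI-mean signal is taken as the
    mean of two "measurements": the ROI as given and a seeded one-voxel
    boundary perturbation of it.
    """
    roi = np.asarray(roi)
    if roi.shape != maps.shape:
        raise ValueError("ROI shape must match the maps")
    in_roi = (roi == label) & maps.mask
    if not in_roi.any():
        raise EmptyRoiError(f"label {label} has no masked-in voxels")

    meas = RoiMeasurement(
        subject_id=subject_id,
        tissue=tissue,
        d=SummaryStats.from_values(maps.D[in_roi]),
        f=SummaryStats.from_values(maps.f[in_roi]),
    )
    if b1000_volume is not None:
        rng = np.random.default_rng(repeat_seed)
        second = perturb_roi(roi == label, rng) & maps.mask
        if not second.any():
            second = in_roi
        m1 = float(b1000_volume[in_roi].mean())
        m2 = float(b1000_volume[second].mean())
        meas.b1000_signal = 0.5 * (m1 + m2)
    return meas


def repeat_cov(first, second) -> float:
    """Within-subject coefficient of variation (%) between paired repeats.

    Per pair: SD of the two values (n-1 denominator) over the pair mean;
    pairs pooled by root-mean-square.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("first/second must be equal-length 1-D sequences")
    means = (a + b) / 2.0
    if np.any(means <= 0):
        raise ValueError("pair means must be positive")
    sds = np.abs(a - b) / np.sqrt(2.0)
    return float(np.sqrt(np.mean((sds / means) ** 2)) * 100.0)


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    u_statistic: float
    p_value: float
    ranges_overlap: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        if not 0.0 <= self.u_statistic <= self.n_a * self.n_b:
            raise ValueError("U out of [0, n_a*n_b]")


#: Largest n1*n2 for which the exact null distribution is enumerated.
EXACT_LIMIT = 400


def mann_whitney(group_a, group_b, variable: str = "") -> GroupComparisonResult:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Exact p by enumeration when n1*n2 <= 400 and there are no ties,
    otherwise the normal approximation with tie correction.  U is the
    statistic for group A with midrank tie handling.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    ra, rb = (float(a.min()), float(a.max())), (float(b.min()), float(b.max()))
    overlap = not (ra[1] < rb[0] or rb[1] < ra[0])
    return GroupComparisonResult(
        variable=variable,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        range_a=ra,
        range_b=rb,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ranges_overlap=overlap,
    )
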