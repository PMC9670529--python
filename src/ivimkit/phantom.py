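"""Synthetic knee-like DWI phantom: nested tissue compartments, the 10-point
acquisition scheme with per-b signal averaging, and Rician noise.

Geometry is a stack of identical axial slices: an inner effusion disc, a
synovial ring around it, a surrounding muscle disc, and zero-signal
background.  Default tissue parameters are the published group means for
arthritis patients and healthy volunteers (D in mm^2/s, f as fraction); the
pseudo-diffusion coefficient defaults to 10*D since no reference value
exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

from .core import BValueScheme, IvimParams, ivim_signal
from .maps import DwiSeries

__all__ = [
    "LABELS",
    "TISSUE_NAMES",
    "GROUP_TISSUE_TABLES",
    "TissueSpec",
    "PhantomSpec",
    "default_tissues",
    "make_label_map",
    "simulate_dwi",
    "cohort_specs",
    "make_cohort",
]

LABELS = {"background": 0, "muscle": 1, "synovium": 2, "effusion": 3}
TISSUE_NAMES = ("muscle", "synovium", "effusion")

#: Group means and between-subject SDs (internal units) plus baseline S0.
GROUP_TISSUE_TABLES = {
    "patients": {
        "muscle": {"D": 1.60e-3, "D_sd": 0.14e-3, "f": 0.069, "f_sd": 0.0205, "S0": 100.0},
        "effusion": {"D": 2.43e-3, "D_sd": 0.41e-3, "f": 0.028, "f_sd": 0.0130, "S0": 150.0},
        "synovium": {"D": 1.81e-3, "D_sd": 0.28e-3, "f": 0.109, "f_sd": 0.0250, "S0": 120.0},
    },
    "volunteers": {
        "muscle": {"D": 1.70e-3, "D_sd": 0.25e-3, "f": 0.074, "f_sd": 0.0260, "S0": 100.0},
        "effusion": {"D": 2.09e-3, "D_sd": 0.44e-3, "f": 0.132, "f_sd": 0.0710, "S0": 150.0},
        "synovium": {"D": 2.61e-3, "D_sd": 0.34e-3, "f": 0.044, "f_sd": 0.0180, "S0": 120.0},
    },
}


@dataclass(frozen=True)
class TissueSpec:
    """Per-compartment generating parameters."""

    name: str
    D: float
    f: float
    Dp: float
    S0: float

    def params(self) -> IvimParams:
        return IvimParams(S0=self.S0, D=self.D, f=self.f, Dp=self.Dp)


def default_tissues(group: str = "patients") -> dict[str, TissueSpec]:
    """Tissue specs at the group means, Dp = 10*D."""
    try:
        table = GROUP_TISSUE_TABLES[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(GROUP_TISSUE_TABLES)}")
    tissues = {
        name: TissueSpec(name=name, D=row["D"], f=row["f"], Dp=10.0 * row["D"], S0=row["S0"])
        for name, row in table.items()
    }
    tissues["background"] = TissueSpec(name="background", D=1e-3, f=0.0, Dp=1e-2, S0=0.0)
    return tissues


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject (geometry + tissues + noise)."""

    shape: tuple[int, int, int] = (64, 64, 5)
    spacing: tuple[float, float, float] = (1.3, 1.3, 3.0)
    center: tuple[float, float] | None = None
    effusion_radius: float = 8.0
    synovium_radius: float = 12.0
    muscle_radius: float = 24.0
    tissues: dict[str, TissueSpec] = field(default_factory=default_tissues)
    sigma: float = 2.0
    seed: int = 0
    scheme: BValueScheme = field(default_factory=BValueScheme)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")
        if not 0.0 <= self.effusion_radius <= self.synovium_radius <= self.muscle_radius:
            raise ValueError("radii must be nested: effusion <= synovium <= muscle")
        if self.muscle_radius <= 0:
            raise ValueError("muscle radius must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        missing = set(LABELS) - set(self.tissues)
        if missing:
            raise ValueError(f"missing tissue specs: {sorted(missing)}")

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    # --- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "center": None if self.center is None else list(self.center),
            "effusion_radius": self.effusion_radius,
            "synovium_radius": self.synovium_radius,
            "muscle_radius": self.muscle_radius,
            "tissues": {
                name: {"D": t.D, "f": t.f, "Dp": t.Dp, "S0": t.S0}
                for name, t in self.tissues.items()
            },
            "sigma": self.sigma,
            "seed": int(self.seed),
            "scheme": {
                "b_values": list(self.scheme.b_values),
                "averages": list(self.scheme.averages),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        tissues = {
            name: TissueSpec(name=name, **row) for name, row in d["tissues"].items()
        }
        scheme = BValueScheme(
            tuple(d["scheme"]["b_values"]), tuple(d["scheme"]["averages"])
        )
        return cls(
            shape=tuple(d["shape"]),
            spacing=tuple(d["spacing"]),
            center=None if d.get("center") is None else tuple(d["center"]),
            effusion_radius=d["effusion_radius"],
            synovium_radius=d["synovium_radius"],
            muscle_radius=d["muscle_radius"],
            tissues=tissues,
            sigma=d["sigma"],
            seed=d["seed"],
            scheme=scheme,
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_label_map(spec: PhantomSpec) -> np.ndarray:
    """Integer label volume from nested-disc membership (deterministic)."""
    nx, ny, nz = spec.shape
    cx, cy = spec.resolved_center()
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    r = np.hypot(x, y)
    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[r <= spec.muscle_radius] = LABELS["muscle"]
    plane[r <= spec.synovium_radius] = LABELS["synovium"]
    plane[r <= spec.effusion_radius] = LABELS["effusion"]
    return np.repeat(plane[:, :, None], nz, axis=2)


def _noiseless_volume(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    """(nx, ny, nz, n_b) noiseless forward-model signal."""
    b = np.asarray(spec.scheme.b_values)
    out = np.zeros(labels.shape + (len(b),))
    for name, lab in LABELS.items():
        region = labels == lab
        if not region.any():
            continue
        out[region] = ivim_signal(spec.tissues[name].params(), b)
    return out


def simulate_dwi(spec: PhantomSpec) -> tuple[DwiSeries, np.ndarray]:
    """Simulate one subject: Rician noise with SD sigma/sqrt(NEX) per b-volume."""
    labels = make_label_map(spec)
    clean = _noiseless_volume(spec, labels)
    if spec.sigma == 0:
        data = clean
    else:
        rng = np.random.default_rng(spec.seed)
        data = np.empty_like(clean)
        for i, nex in enumerate(spec.scheme.averages):
            s_eff = spec.sigma / np.sqrt(nex)
            n1 = rng.normal(0.0, s_eff, size=clean.shape[:-1])
            n2 = rng.normal(0.0, s_eff, size=clean.shape[:-1])
            data[..., i] = np.hypot(clean[..., i] + n1, n2)
    series = DwiSeries(scheme=spec.scheme, data=data, spacing=spec.spacing)
    return series, labels


def _truncated_normal(mean: float, sd: float, trunc: float, rng) -> float:
    if sd == 0:
        return mean
    return float(truncnorm.rvs(-trunc, trunc, loc=mean, scale=sd, random_state=rng))


def cohort_specs(
    n_subjects: int,
    group: str,
    base_seed: int,
    *,
    jitter_scale: float = 1.0,
    jitter_trunc: float = 1.0,
    sigma: float = 2.0,
    shape: tuple[int, int, int] = (64, 64, 5),
) -> list[PhantomSpec]:
    """Per-subject specs with tissue parameters jittered around the group
    means (truncated Gaussian, SD = published between-subject SD *
    jitter_scale, truncated at +/- jitter_trunc SD).  Deterministic given
    base_seed; subjects get independent child seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    table = GROUP_TISSUE_TABLES.get(group)
    if table is None:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(GROUP_TISSUE_TABLES)}")
    children = np.random.SeedSequence(base_seed).spawn(n_subjects)
    specs = []
    for child in children:
        rng = np.random.default_rng(child)
        tissues = {"background": default_tissues(group)["background"]}
        for name, row in table.items():
            d = _truncated_normal(row["D"], row["D_sd"] * jitter_scale, jitter_trunc, rng)
            f = _truncated_normal(row["f"], row["f_sd"] * jitter_scale, jitter_trunc, rng)
            tissues[name] = TissueSpec(name=name, D=d, f=f, Dp=10.0 * d, S0=row["S0"])
        specs.append(
            PhantomSpec(
                shape=shape,
                tissues=tissues,
                sigma=sigma,
                seed=int(child.generate_state(1)[0]),
            )
        )
    return specs


def make_cohort(
    n_subjects: int, group: str, base_seed: int, **kwargs
) -> list[tuple[DwiSeries, np.ndarray]]:
    """Simulate a cohort; returns (series, label volume) per subject."""
    return [simulate_dwi(spec) for spec in cohort_specs(n_subjects, group, base_seed, **kwargs)]
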