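"""End-to-end orchestration: phantom cohorts -> maps -> ROI stats -> group
tests -> agreement report, with a seed/config-hash manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_report, read_ratings_csv, study_fixture
from .core import FitConfig
from .io import save_dwi_series, save_nifti, save_parameter_maps
from .maps import fit_volume
from .phantom import LABELS, TISSUE_NAMES, cohort_specs, simulate_dwi
from .roi import extract_roi_stats, mann_whitney

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

GROUPS = ("patients", "volunteers")


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "ivimkit_run"
    seed: int = 0
    n_per_group: int = 10
    shape: tuple[int, int, int] = (64, 64, 5)
    sigma: float = 2.0
    jitter_scale: float = 1.0
    fit: FitConfig = field(default_factory=FitConfig)
    ratings_csv: str | None = None  # None -> use the built-in study fixture
    write_maps: bool = True  # export NIfTI maps for the first subject per group
    write_series: bool = False

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": int(self.seed),
            "n_per_group": self.n_per_group,
            "shape": list(self.shape),
            "sigma": self.sigma,
            "jitter_scale": self.jitter_scale,
            "fit": self.fit.to_dict(),
            "ratings_csv": self.ratings_csv,
            "write_maps": self.write_maps,
            "write_series": self.write_series,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitConfig.from_dict(d["fit"])
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _measure_cohort(cfg: RunConfig, group: str, out_dir: Path) -> list[dict]:
    specs = cohort_specs(
        cfg.n_per_group,
        group,
        base_seed=cfg.seed + (0 if group == "patients" else 1_000_000),
        jitter_scale=cfg.jitter_scale,
        sigma=cfg.sigma,
        shape=cfg.shape,
    )
    rows = []
    for i, spec in enumerate(specs):
        subject = f"{group[:-1]}_{i:02d}"
        series, labels = simulate_dwi(spec)
        maps = fit_volume(series, cfg.fit)
        if cfg.write_series:
            save_dwi_series(series, out_dir / f"{subject}_dwi.nii.gz")
        if cfg.write_maps and i == 0:
            save_parameter_maps(maps, out_dir / f"{subject}_maps", spec.spacing)
            save_nifti(labels, out_dir / f"{subject}_labels.nii.gz", spec.spacing)
        b1000 = series.volume(1000.0) if 1000.0 in series.scheme.b_values else None
        for tissue in TISSUE_NAMES:
            meas = extract_roi_stats(
                maps,
                labels,
                LABELS[tissue],
                subject_id=subject,
                tissue=tissue,
                b1000_volume=b1000,
                repeat_seed=cfg.seed + i,
            )
            truth = spec.tissues[tissue]
            rows.append(
                {
                    "group": group,
                    "subject": subject,
                    "tissue": tissue,
                    "n_voxels": meas.d.count,
                    # export units: D in 1e-3 mm^2/s, f in %
                    "D_mean": meas.d.mean * 1e3,
                    "D_sd": meas.d.sd * 1e3,
                    "D_min": meas.d.min * 1e3,
                    "D_max": meas.d.max * 1e3,
                    "f_mean": meas.f.mean * 100.0,
                    "f_sd": meas.f.sd * 100.0,
                    "f_min": meas.f.min * 100.0,
                    "f_max": meas.f.max * 100.0,
                    "b1000_signal": meas.b1000_signal,
                    "true_D": truth.D * 1e3,
                    "true_f": truth.f * 100.0,
                }
            )
    return rows


def _group_tests(measurements: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    summary_rows, test_results = [], []
    for tissue in TISSUE_NAMES:
        for var in ("D_mean", "f_mean"):
            a = measurements.query("group == 'patients' and tissue == @tissue")[var].to_numpy()
            b = measurements.query("group == 'volunteers' and tissue == @tissue")[var].to_numpy()
            res = mann_whitney(a, b, variable=f"{tissue}.{var}")
            summary_rows.append(
                {
                    "tissue": tissue,
                    "variable": var,
                    "patients_mean": res.mean_a,
                    "patients_sd": res.sd_a,
                    "volunteers_mean": res.mean_b,
                    "volunteers_sd": res.sd_b,
                    "patients_min": res.range_a[0],
                    "patients_max": res.range_a[1],
                    "volunteers_min": res.range_b[0],
                    "volunteers_max": res.range_b[1],
                    "U": res.u_statistic,
                    "p_value": res.p_value,
                    "ranges_overlap": res.ranges_overlap,
                }
            )
            test_results.append(
                {
                    "variable": res.variable,
                    "U": res.u_statistic,
                    "p_value": res.p_value,
                    "ranges_overlap": res.ranges_overlap,
                }
            )
    return pd.DataFrame(summary_rows), test_results


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full demo analysis; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    stage = "simulate_and_fit"
    try:
        log.info("stage %s", stage)
        rows = []
        for group in GROUPS:
            rows.extend(_measure_cohort(cfg, group, out_dir))
        measurements = pd.DataFrame(rows)
        meas_path = out_dir / "measurements.csv"
        measurements.to_csv(meas_path, index=False)
        outputs["measurements"] = meas_path.name
    except Exception as exc:  # noqa: BLE001 - report stage and abort cleanly
        raise PipelineError(stage, exc) from exc

    stage = "group_comparison"
    try:
        log.info("stage %s", stage)
        summary, tests = _group_tests(measurements)
        summary_path = out_dir / "group_summary.csv"
        summary.to_csv(summary_path, index=False)
        outputs["group_summary"] = summary_path.name
        tests_path = out_dir / "group_tests.json"
        tests_path.write_text(json.dumps(tests, indent=2))
        outputs["group_tests"] = tests_path.name
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "reader_agreement"
    try:
        log.info("stage %s", stage)
        records = (
            read_ratings_csv(cfg.ratings_csv) if cfg.ratings_csv else study_fixture()
        )
        report = agreement_report(records)
        agr_path = out_dir / "agreement.json"
        agr_path.write_text(json.dumps(report, indent=2))
        outputs["agreement"] = agr_path.name
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "manifest"
    try:
        manifest = {
            "software": "ivimkit",
            "version": __version__,
            "seed": int(cfg.seed),
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "outputs": outputs,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc
    return manifest
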