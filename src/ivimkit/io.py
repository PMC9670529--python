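"""NIfTI / sidecar I/O and export-unit scaling.

Internal units are mm^2/s and fraction; exported maps follow the common
reporting convention: D, Dp and ADC in 1e-3 mm^2/s, f in percent.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BValueScheme
from .maps import DwiSeries, ParameterMapSet

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bvals",
    "read_bvals",
    "save_dwi_series",
    "load_dwi_series",
    "save_parameter_maps",
]

#: Export scale factors per map name.
EXPORT_SCALE = {"D": 1e3, "Dp": 1e3, "adc": 1e3, "f": 100.0}


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(array: np.ndarray, path, spacing=(1.3, 1.3, 3.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), spacing


def write_bvals(scheme: BValueScheme, path) -> Path:
    """FSL-style bval sidecar (one space-separated line) plus an adjacent
    ``.scheme.json`` carrying the averages."""
    path = Path(path)
    path.write_text(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")
    meta = {"b_values": list(scheme.b_values), "averages": list(scheme.averages)}
    path.with_suffix(".scheme.json").write_text(json.dumps(meta))
    return path


def read_bvals(path) -> BValueScheme:
    path = Path(path)
    meta_path = path.with_suffix(".scheme.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        return BValueScheme(tuple(meta["b_values"]), tuple(meta["averages"]))
    b_values = tuple(float(x) for x in path.read_text().split())
    return BValueScheme(b_values, (1,) * len(b_values))


def save_dwi_series(series: DwiSeries, nifti_path, bval_path=None) -> Path:
    nifti_path = Path(nifti_path)
    save_nifti(series.data, nifti_path, series.spacing)
    if bval_path is None:
        stem = nifti_path.name.removesuffix(".gz").removesuffix(".nii")
        bval_path = nifti_path.parent / (stem + ".bval")
    write_bvals(series.scheme, bval_path)
    return nifti_path


def load_dwi_series(nifti_path, bval_path) -> DwiSeries:
    data, spacing = load_nifti(nifti_path)
    scheme = read_bvals(bval_path)
    return DwiSeries(scheme=scheme, data=data, spacing=spacing)


def save_parameter_maps(maps: ParameterMapSet, out_dir, spacing=(1.3, 1.3, 3.0)) -> dict:
    """Write D/f/Dp/ADC maps (export units) and the mask; returns name->path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {"D": maps.D, "f": maps.f, "Dp": maps.Dp, "adc": maps.adc}
    written = {}
    for name, arr in arrays.items():
        p = out_dir / f"{name}_map.nii.gz"
        save_nifti(arr * EXPORT_SCALE[name], p, spacing)
        written[name] = p
    mask_path = out_dir / "mask.nii.gz"
    save_nifti(maps.mask.astype(np.uint8), mask_path, spacing)
    written["mask"] = mask_path
    return written
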