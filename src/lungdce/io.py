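"""NIfTI / CSV / JSON plumbing, provenance and manifests.

Volumes are NIfTI-1 (4D float32 series, uint8 masks and label maps). The
frame interval is carried in a JSON sidecar (``<name>.json``) rather than
the NIfTI time header, which is unreliable across tools; it may also be
supplied explicitly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError
from .series import DynamicSeries, validate_mask


def _affine(voxel_size_mm):
    return np.diag([*voxel_size_mm, 1.0])


def write_series(series: DynamicSeries, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32),
                          _affine(series.voxel_size_mm))
    img.header.set_zooms((*series.voxel_size_mm, series.dt_s))
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {"dt_s": series.dt_s, "voxel_size_mm": list(series.voxel_size_mm)}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta))
    return path


def read_series(path, dt_s: float | None = None) -> DynamicSeries:
    """Load a 4D NIfTI series; timing from the sidecar unless given."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"expected a 4D series, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    if dt_s is None:
        if sidecar.exists():
            dt_s = float(json.loads(sidecar.read_text())["dt_s"])
        elif len(zooms) >= 4 and zooms[3] > 0:
            dt_s = float(zooms[3])
        else:
            raise ValidationError("frame interval missing: supply dt_s")
    return DynamicSeries(data=data.astype(float), dt_s=dt_s,
                         voxel_size_mm=tuple(float(z) for z in zooms[:3]))


def write_mask(mask: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def read_mask(path) -> np.ndarray:
    data = np.asanyarray(nib.load(path).dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D mask, got {data.ndim}D: {path}")
    return validate_mask(data, name=str(path))


def read_labels(path) -> np.ndarray:
    data = np.asanyarray(nib.load(path).dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D label map, got {data.ndim}D: {path}")
    return data.astype(np.int32)


def write_map(volume: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def write_aif(aif, out_dir: Path, stem: str = "aif") -> list[Path]:
    """AIF as CSV (frame, time_s, value) plus a JSON scalar summary."""
    out_dir = Path(out_dir)
    csv_path = out_dir / f"{stem}.csv"
    with open(csv_path, "w") as fh:
        fh.write("frame,time_s,value\n")
        for i, (t, v) in enumerate(zip(aif.times_s, aif.values)):
            fh.write(f"{i},{t:.4f},{v:.8g}\n")
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps({
        "integral": aif.integral, "peak_frame": aif.peak_frame,
        "arrival_frame": aif.arrival_frame,
        "source_voxel_count": aif.source_voxel_count,
    }, indent=2))
    return [csv_path, json_path]


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, config: dict, seed: int | None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(
        {"lungdce_version": __version__, "seed": seed, "config": config},
        indent=2, default=str))
    return path


def write_manifest(out_dir, files: list[Path]) -> Path:
    out_dir = Path(out_dir)
    manifest = {str(Path(f).relative_to(out_dir)): sha256(f) for f in files}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
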