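"""File I/O: NIfTI volumes, curve CSVs, ground-truth sidecars, manifests.

Volumes travel as NIfTI (.nii or .nii.gz) with the voxel spacing in
the header zooms; 4D dynamic series carry their frame times in a JSON
sidecar.  Curves are two-column CSVs (time_s, value).  Cohort exports
write one directory per tumor-day with a manifest CSV tying files to
metadata and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicSeries, TimeCurve, ValidationError
from .phantom import CohortScan

__all__ = [
    "write_volume",
    "read_volume",
    "write_series",
    "read_series",
    "write_curve_csv",
    "read_curve_csv",
    "export_cohort",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path, volume: np.ndarray, spacing) -> None:
    """Write a 3D volume (or boolean mask) as NIfTI with spacing in mm."""
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, _affine(spacing)), str(path))


def read_volume(path):
    """Read a NIfTI volume; returns ``(data, spacing)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_series(path, series: DynamicSeries) -> None:
    """Write a 4D dynamic series as NIfTI plus a frame-times JSON
    sidecar (same stem, ``.times.json``)."""
    path = Path(path)
    # store as (z, y, x, t) which is the conventional NIfTI axis order
    nib.save(
        nib.Nifti1Image(np.moveaxis(series.data, 0, -1), _affine(series.spacing)),
        str(path),
    )
    sidecar = path.parent / (path.name.split(".")[0] + ".times.json")
    sidecar.write_text(json.dumps({"frame_times_s": series.frame_times.tolist()}))


def read_series(path) -> DynamicSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"{path} is not a 4D series")
    sidecar = path.parent / (path.name.split(".")[0] + ".times.json")
    if not sidecar.exists():
        raise ValidationError(f"frame-times sidecar {sidecar} not found")
    times = json.loads(sidecar.read_text())["frame_times_s"]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicSeries(np.moveaxis(data, -1, 0), np.asarray(times), spacing)


def write_curve_csv(path, curve: TimeCurve) -> None:
    pd.DataFrame({"time_s": curve.times, "value": curve.values}).to_csv(
        path, index=False
    )


def read_curve_csv(path, kind: str = "raw") -> TimeCurve:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("curve CSV needs two columns (time_s, value)")
    return TimeCurve(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), kind=kind
    )


def export_cohort(scans: list[CohortScan], out_dir) -> Path:
    """Write a simulated cohort to disk; returns the manifest path.

    Per scan: the dynamic series, tumor and aorta masks, the SUV
    volume, and a ground-truth JSON sidecar.  The manifest CSV has one
    row per tumor-day with metadata, file paths and ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        stem = f"{scan.tumor_id}_d{scan.day:02d}"
        sub = out / stem
        sub.mkdir(exist_ok=True)
        write_series(sub / "series.nii.gz", scan.series)
        write_volume(sub / "tumor_mask.nii.gz", scan.tumor_mask, scan.series.spacing)
        write_volume(sub / "aorta_mask.nii.gz", scan.aorta_mask, scan.series.spacing)
        write_volume(sub / "suv.nii.gz", scan.suv_volume, scan.series.spacing)
        (sub / "truth.json").write_text(json.dumps(scan.truth, indent=1))
        rows.append(
            dict(
                rabbit_id=scan.rabbit_id,
                tumor_id=scan.tumor_id,
                group=scan.group,
                day=scan.day,
                series=str(sub / "series.nii.gz"),
                tumor_mask=str(sub / "tumor_mask.nii.gz"),
                aorta_mask=str(sub / "aorta_mask.nii.gz"),
                suv=str(sub / "suv.nii.gz"),
                **{f"true_{k}": v for k, v in scan.truth.items()},
            )
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
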