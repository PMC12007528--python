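"""Standard-format I/O: single-slice NIfTI image series, TSV tables, HDF5
k-space containers."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionSchedule, KSpaceSeries
from .analysis import ROIResponse
from .recon import ImageSeries

__all__ = [
    "save_image_series",
    "load_image_series",
    "save_mask",
    "save_map",
    "save_roi_response",
    "save_kspace",
    "load_kspace",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag([voxel_size_mm[0], voxel_size_mm[1], voxel_size_mm[2], 1.0])


def save_image_series(series: ImageSeries, path: str | Path) -> Path:
    """Write a run as single-slice 4D NIfTI (x, y, 1, t)."""
    path = Path(path)
    vol = np.transpose(series.data, (2, 1, 0))[:, :, None, :]  # (x, y, 1, t)
    img = nib.Nifti1Image(vol.astype(np.float32), _affine(series.voxel_size_mm))
    img.header.set_zooms(series.voxel_size_mm + (series.tr_ms / 1000.0,))
    nib.save(img, str(path))
    return path


def load_image_series(path: str | Path, tr_ms: float | None = None) -> ImageSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim == 3:
        vol = vol[..., None, :] if vol.shape[2] > 4 else vol[..., None]
    if vol.ndim != 4 or vol.shape[2] != 1:
        raise ValueError("expected a single-slice 4D NIfTI (x, y, 1, t)")
    data = np.transpose(vol[:, :, 0, :], (2, 1, 0))
    zooms = img.header.get_zooms()
    if tr_ms is None:
        tr_ms = float(zooms[3]) * 1000.0 if len(zooms) > 3 and zooms[3] > 0 else 5.0
    voxel = tuple(float(z) for z in zooms[:3])
    return ImageSeries(data=data, tr_ms=tr_ms, voxel_size_mm=voxel)


def save_mask(mask: np.ndarray, path: str | Path, voxel_size_mm=(2.0, 2.0, 5.0)) -> Path:
    path = Path(path)
    vol = np.transpose(np.asarray(mask, dtype=np.uint8), (1, 0))[:, :, None]
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size_mm)), str(path))
    return path


def save_map(map2d: np.ndarray, path: str | Path, voxel_size_mm=(2.0, 2.0, 5.0)) -> Path:
    path = Path(path)
    vol = np.transpose(np.asarray(map2d, dtype=np.float32), (1, 0))[:, :, None]
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size_mm)), str(path))
    return path


def save_roi_response(response: ROIResponse, path: str | Path) -> Path:
    """ROI time course as TSV: time_ms, mean_pct, ci_lo, ci_hi, n_runs."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ms": response.time_ms,
            "mean_pct": response.mean,
            "ci_lo": response.ci_lower,
            "ci_hi": response.ci_upper,
            "n_runs": response.n_runs,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def save_kspace(kspace: KSpaceSeries, path: str | Path) -> Path:
    """Persist a k-space run with its schedule metadata in HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=kspace.data)
        f.create_dataset("filled", data=kspace.filled)
        sch = kspace.schedule
        g = f.create_group("schedule")
        for name in ("phase_line", "time_point", "trial_index", "absolute_time_s"):
            g.create_dataset(name, data=getattr(sch, name))
        g.attrs.update(
            mode=sch.mode,
            n_lines=sch.n_lines,
            n_timepoints=sch.n_timepoints,
            tr_ms=sch.tr_ms,
            n_dummy=sch.n_dummy,
            start_time_s=sch.start_time_s,
        )
    return path


def load_kspace(path: str | Path) -> KSpaceSeries:
    with h5py.File(path, "r") as f:
        g = f["schedule"]
        schedule = AcquisitionSchedule(
            mode=str(g.attrs["mode"]),
            n_lines=int(g.attrs["n_lines"]),
            n_timepoints=int(g.attrs["n_timepoints"]),
            tr_ms=float(g.attrs["tr_ms"]),
            n_dummy=int(g.attrs["n_dummy"]),
            start_time_s=float(g.attrs["start_time_s"]),
            phase_line=g["phase_line"][()],
            time_point=g["time_point"][()],
            trial_index=g["trial_index"][()],
            absolute_time_s=g["absolute_time_s"][()],
        )
        return KSpaceSeries(
            data=f["data"][()], schedule=schedule, filled=f["filled"][()]
        )
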