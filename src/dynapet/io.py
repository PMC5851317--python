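"""Standard-format I/O: NIfTI image series, frame-timing CSV, TAC/fit tables.

A dynamic series is stored as one 3D NIfTI file with frames along the last
axis (voxel size in the header) plus a sidecar CSV with columns
``frame_index, start_s, duration_s``.  Quantification can therefore run on
externally produced images with the same layout.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import FrameSchedule, DynamicImageSeries

__all__ = [
    "save_series",
    "load_series",
    "save_tac",
    "load_config",
    "dump_config",
]


def save_series(series: DynamicImageSeries, image_path, timing_path=None) -> None:
    """Write a dynamic series as NIfTI + frame-timing sidecar CSV."""
    image_path = Path(image_path)
    if timing_path is None:
        stem = image_path.name.removesuffix(".gz").removesuffix(".nii")
        timing_path = image_path.with_name(stem + "_frames.csv")
    # (ny, nx, n_frames) with voxel size in the affine / zooms
    vol = np.moveaxis(series.data, 0, -1)
    affine = np.diag([series.voxel_size_mm, series.voxel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
    img.header.set_zooms((series.voxel_size_mm, series.voxel_size_mm, 1.0))
    nib.save(img, image_path)
    sched = series.schedule
    pd.DataFrame({
        "frame_index": np.arange(sched.n_frames),
        "start_s": sched.starts,
        "duration_s": sched.durations,
    }).to_csv(timing_path, index=False)


def load_series(image_path, timing_path, decay_corrected: bool = True) -> DynamicImageSeries:
    """Load a dynamic series from NIfTI + frame-timing CSV."""
    img = nib.load(str(image_path))
    vol = np.asarray(img.get_fdata(), dtype=float)
    data = np.moveaxis(vol, -1, 0)
    voxel = float(img.header.get_zooms()[0])
    timing = pd.read_csv(timing_path)
    schedule = FrameSchedule(starts=timing["start_s"].to_numpy(dtype=float),
                             durations=timing["duration_s"].to_numpy(dtype=float))
    return DynamicImageSeries(data=data, schedule=schedule, voxel_size_mm=voxel,
                              decay_corrected=decay_corrected)


def save_tac(tac, path) -> None:
    tac.to_frame().to_csv(path, index=False)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        import json

        return json.load(fh)


def dump_config(config: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config, fh, sort_keys=False)
        else:
            import json

            json.dump(config, fh, indent=2)
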