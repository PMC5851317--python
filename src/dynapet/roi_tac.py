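"""ROI definition, time-activity curves, SUV, and CV/contrast image metrics.

The ROI scheme mirrors the clinical protocol: four 5 mm-diameter myocardial
ROIs spread along the LV wall (pooled for statistics), one 10 mm ROI in the
LV blood pool (image-derived input function and contrast background) and one
10 mm ROI in the RV blood pool (spillover correction).

CV and contrast are the standard image-quality surrogates

    CV       = signal SD / signal mean
    contrast = (signal mean - background mean) / background mean

with the population (n) standard deviation over signal voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import DynamicImageSeries, voxel_centers

__all__ = [
    "ROISpec",
    "TimeActivityCurve",
    "ROIStatistics",
    "SUVReport",
    "make_roi_mask",
    "extract_tac",
    "roi_statistics",
    "compute_suv",
    "convergence_curve",
    "default_roi_set",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular (2D section of spherical) ROI in scanner mm coordinates."""

    name: str
    center_mm: tuple[float, float]
    diameter_mm: float
    role: str  # myocardium | lv_blood | rv_blood

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.role not in ("myocardium", "lv_blood", "rv_blood"):
            raise ValueError(f"unknown ROI role {self.role!r}")


@dataclass
class TimeActivityCurve:
    """Activity concentration vs frame mid-time for one ROI (or pooled ROIs)."""

    times_min: np.ndarray
    values: np.ndarray
    durations_min: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.durations_min = np.asarray(self.durations_min, dtype=float)
        if not (self.times_min.size == self.values.size == self.durations_min.size):
            raise ValueError("TAC arrays must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("TAC times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_min": self.times_min,
            "duration_min": self.durations_min,
            "value_kBq_per_mL": self.values,
        })


@dataclass(frozen=True)
class ROIStatistics:
    signal_mean: float
    signal_sd: float
    background_mean: float

    @property
    def cv(self) -> float:
        return self.signal_sd / self.signal_mean

    @property
    def contrast(self) -> float:
        return (self.signal_mean - self.background_mean) / self.background_mean


@dataclass
class SUVReport:
    times_min: np.ndarray
    suv_mean: np.ndarray
    injected_dose_MBq: float
    body_weight_g: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.times_min, "suv_mean": self.suv_mean})


def make_roi_mask(roi: ROISpec, grid: tuple[int, int], voxel_size_mm: float) -> np.ndarray:
    """Boolean voxel mask; a voxel is included iff its center is inside the ROI."""
    X, Y = voxel_centers(grid, voxel_size_mm)
    r2 = (X - roi.center_mm[0]) ** 2 + (Y - roi.center_mm[1]) ** 2
    mask = r2 <= (roi.diameter_mm / 2.0) ** 2
    if not np.any(mask):
        raise ValueError(f"ROI {roi.name!r} covers no voxel center")
    return mask


def extract_tac(series: DynamicImageSeries, masks) -> TimeActivityCurve:
    """Per-frame mean over the union of the given masks (voxel pooling).

    Pooling the voxels of the four myocardial ROIs equals the mean of the
    per-ROI means when the ROIs have equal voxel counts.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    union = np.zeros(series.data.shape[1:], dtype=bool)
    for m in masks:
        union |= np.asarray(m, dtype=bool)
    if not np.any(union):
        raise ValueError("mask union is empty")
    values = series.data[:, union].mean(axis=1)
    sched = series.schedule
    return TimeActivityCurve(
        times_min=sched.mid_times / 60.0,
        values=values,
        durations_min=sched.durations / 60.0,
    )


def roi_statistics(image: np.ndarray, signal_mask: np.ndarray,
                   background_mask: np.ndarray) -> ROIStatistics:
    """Signal mean/SD and background mean for CV and contrast."""
    sig = np.asarray(image)[np.asarray(signal_mask, dtype=bool)]
    bkg = np.asarray(image)[np.asarray(background_mask, dtype=bool)]
    if sig.size == 0 or bkg.size == 0:
        raise ValueError("signal and background masks must be nonempty")
    s_mean = float(sig.mean())
    b_mean = float(bkg.mean())
    if s_mean == 0:
        raise ValueError("zero signal mean: CV undefined")
    if b_mean == 0:
        raise ValueError("zero background mean: contrast undefined")
    return ROIStatistics(signal_mean=s_mean, signal_sd=float(sig.std(ddof=0)),
                         background_mean=b_mean)


def compute_suv(tac: TimeActivityCurve, dose_MBq: float, weight_g: float,
                times_min) -> SUVReport:
    """SUV_mean at the requested times from the frame containing each time.

    SUV = concentration [kBq/mL] / (dose [kBq] / weight [g]) assuming tissue
    density 1 g/mL.
    """
    if dose_MBq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be positive")
    times = np.atleast_1d(np.asarray(times_min, dtype=float))
    starts = tac.times_min - 0.5 * tac.durations_min
    ends = tac.times_min + 0.5 * tac.durations_min
    conc = np.empty(times.size)
    for i, t in enumerate(times):
        hit = np.flatnonzero((starts <= t) & (t < ends + 1e-12))
        if hit.size == 0:
            raise ValueError(f"time point {t} min outside the scanned frames")
        conc[i] = tac.values[hit[0]]
    suv = conc / (dose_MBq * 1000.0 / weight_g)
    return SUVReport(times_min=times, suv_mean=suv,
                     injected_dose_MBq=dose_MBq, body_weight_g=weight_g)


def convergence_curve(snapshots, signal_mask, background_mask) -> pd.DataFrame:
    """CV/contrast per reconstruction snapshot.

    ``snapshots`` is an iterable of (em_equivalent_iteration, image).
    """
    rows = []
    for em_iter, image in snapshots:
        stats = roi_statistics(image, signal_mask, background_mask)
        rows.append(dict(em_equivalent=em_iter, cv=stats.cv, contrast=stats.contrast,
                         signal_mean=stats.signal_mean, signal_sd=stats.signal_sd,
                         background_mean=stats.background_mean))
    return pd.DataFrame(rows)


def default_roi_set(lv_center=(-12.0, 0.0), myo_radius_mm: float = 15.0,
                    rv_center=(17.0, 4.0)) -> list[ROISpec]:
    """Clinical ROI layout for the default phantom.

    Four 5 mm myocardial ROIs at 0/90/180/270 degrees on a circle of
    ``myo_radius_mm`` around the LV center (mid-wall of the default annulus),
    plus 10 mm LV and RV blood-pool ROIs.
    """
    rois = []
    for i, ang in enumerate([0.0, 90.0, 180.0, 270.0]):
        a = np.deg2rad(ang)
        c = (lv_center[0] + myo_radius_mm * np.cos(a),
             lv_center[1] + myo_radius_mm * np.sin(a))
        rois.append(ROISpec(f"myo_{i + 1}", c, 5.0, "myocardium"))
    rois.append(ROISpec("lv_blood", tuple(lv_center), 10.0, "lv_blood"))
    rois.append(ROISpec("rv_blood", tuple(rv_center), 10.0, "rv_blood"))
    return rois
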