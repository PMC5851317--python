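"""Synthetic 2D cardiac phantom with 1-tissue-compartment regional kinetics.

The phantom is a single transaxial slice through the heart: left-ventricular
(LV) blood pool, right-ventricular (RV) blood pool, a myocardial annulus
around the LV cavity, and a water-equivalent body background.  Regional
activity follows either the arterial input function directly (blood pools,
the RV optionally leading the LV by a short transit time) or the
1-tissue-compartment model driven by that input (tissue).  Physical decay of
11C is applied so that the generated frames are *not* decay corrected, like
raw scanner frames.

Units: space in mm, attenuation in 1/cm, activity concentration in kBq/mL,
schedule times in seconds, kinetic rate constants per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import simpson

__all__ = [
    "HALF_LIFE_C11_MIN",
    "FrameSchedule",
    "InputFunctionParams",
    "Region",
    "PhantomSpec",
    "DynamicImageSeries",
    "build_frame_schedule",
    "evaluate_input_function",
    "rasterize_phantom",
    "make_dynamic_truth",
    "cardiac_phantom",
    "default_input_function",
    "default_schedule_blocks",
]

#: 11C physical half-life as used throughout the pipeline (minutes).  The
#: rounded clinical value is used; the exact physical value is 20.364 min.
HALF_LIFE_C11_MIN = 20.0

#: Dynamic framing protocol: 15x10 s, 15x30 s, 16x60 s, 7x120 s = 53 frames,
#: 40 minutes.
DEFAULT_SCHEDULE_BLOCKS = [(15, 10.0), (15, 30.0), (16, 60.0), (7, 120.0)]


def default_schedule_blocks() -> list[tuple[int, float]]:
    return list(DEFAULT_SCHEDULE_BLOCKS)


class InvalidProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic framing protocol.

    ``starts``/``durations`` are in seconds with the injection at t = 0.
    """

    starts: np.ndarray
    durations: np.ndarray
    injection_time: float = 0.0

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.size == 0:
            raise InvalidProtocolError("schedule must contain at least one frame")
        if starts[0] != 0.0:
            raise InvalidProtocolError("first frame must start at t=0")
        if np.any(durations <= 0):
            raise InvalidProtocolError("frame durations must be positive")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise InvalidProtocolError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1])

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return self.starts + 0.5 * self.durations

    def frame_containing(self, t_s: float) -> int:
        """Index of the frame whose interval [start, end) contains ``t_s``."""
        if t_s < 0 or t_s > self.total_duration:
            raise ValueError(f"time {t_s} s outside the scan [0, {self.total_duration}]")
        idx = int(np.searchsorted(self.ends, t_s, side="right"))
        return min(idx, self.n_frames - 1)


def build_frame_schedule(blocks: list[tuple[int, float]]) -> FrameSchedule:
    """Expand ``(count, duration_s)`` blocks into a contiguous frame schedule.

    The clinical acetate protocol ``[(15,10),(15,30),(16,60),(7,120)]`` yields
    53 frames covering 40 minutes.
    """
    if not blocks:
        raise InvalidProtocolError("empty block list")
    durations = []
    for count, dur in blocks:
        if count < 1:
            raise InvalidProtocolError(f"block count must be >= 1, got {count}")
        if dur <= 0:
            raise InvalidProtocolError(f"block duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    durations = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts=starts, durations=durations)


# ---------------------------------------------------------------------------
# Arterial input function models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunctionParams:
    """Parametric arterial input function C_P(t).

    models
        ``feng``
            4-exponential bolus model
            ``(a1*(t) - a2 - a3) e^{l1 t} + a2 e^{l2 t} + a3 e^{l3 t}``
            with t in minutes past ``delay_s``; ``a1`` in kBq/mL/min, ``a2``,
            ``a3`` in kBq/mL and ``l1..l3`` non-positive rates per minute.
        ``gamma_variate``
            ``amplitude * t^alpha * exp(-t/beta)`` with t in minutes past
            ``delay_s``.
        ``constant``
            constant ``value`` after ``delay_s`` (testing / calibration).

    The curve is identically zero before ``delay_s``.
    """

    model: str = "feng"
    params: dict = field(default_factory=lambda: dict(DEFAULT_FENG_PARAMS))
    delay_s: float = 10.0


#: Feng-style bolus coefficients scaled so the peak is ~150 kBq/mL, a typical
#: LV blood-pool concentration after a ~740 MBq acetate injection.
DEFAULT_FENG_PARAMS = {
    "a1": 1700.0,   # kBq/mL/min
    "a2": 1.2,      # kBq/mL
    "a3": 1.1,      # kBq/mL
    "l1": -4.1339,  # 1/min
    "l2": -0.1191,  # 1/min
    "l3": -0.01043, # 1/min
}


def _feng(t_min: np.ndarray, p: dict) -> np.ndarray:
    a1, a2, a3 = p["a1"], p["a2"], p["a3"]
    l1, l2, l3 = p["l1"], p["l2"], p["l3"]
    if a1 < 0 or a2 < 0 or a3 < 0:
        raise ValueError("feng amplitudes must be nonnegative")
    if l1 > 0 or l2 > 0 or l3 > 0:
        raise ValueError("feng exponents must be non-positive rates")
    return (a1 * t_min - a2 - a3) * np.exp(l1 * t_min) + a2 * np.exp(l2 * t_min) + a3 * np.exp(l3 * t_min)


def _gamma_variate(t_min: np.ndarray, p: dict) -> np.ndarray:
    amp, alpha, beta = p["amplitude"], p["alpha"], p["beta"]
    if amp < 0 or alpha <= 0 or beta <= 0:
        raise ValueError("gamma-variate parameters must be positive")
    with np.errstate(invalid="ignore"):
        out = amp * np.power(t_min, alpha) * np.exp(-t_min / beta)
    return np.where(t_min > 0, out, 0.0)


def evaluate_input_function(params: InputFunctionParams, times_s) -> np.ndarray:
    """Evaluate C_P at ``times_s`` (seconds); returns kBq/mL, zero pre-delay."""
    t = np.atleast_1d(np.asarray(times_s, dtype=float))
    t_min = (t - params.delay_s) / 60.0
    active = t_min >= 0
    out = np.zeros_like(t)
    if np.any(active):
        tm = t_min[active]
        if params.model == "feng":
            vals = _feng(tm, params.params)
        elif params.model == "gamma_variate":
            vals = _gamma_variate(tm, params.params)
        elif params.model == "constant":
            vals = np.full_like(tm, float(params.params["value"]))
        else:
            raise ValueError(f"unknown input-function model {params.model!r}")
        peak = float(np.max(vals)) if vals.size else 0.0
        if np.any(vals < -1e-9 * max(peak, 1.0)):
            raise ValueError("input-function parameters imply negative activity")
        out[active] = np.clip(vals, 0.0, None)
    return out


def default_input_function() -> InputFunctionParams:
    return InputFunctionParams()


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """One geometric phantom region.

    ``shape`` is ``full`` (whole grid), ``disc`` (``center_mm``/``radius_mm``)
    or ``annulus`` (``center_mm``/``inner_radius_mm``/``outer_radius_mm``).
    ``kinetics`` is ``("blood", time_shift_s)`` — the region follows the input
    curve evaluated at ``t + time_shift_s`` — or ``("tissue", K1, k2)`` with
    K1 in mL/min/mL and k2 in 1/min.
    """

    name: str
    shape: str
    center_mm: tuple[float, float] = (0.0, 0.0)
    radius_mm: float | None = None
    inner_radius_mm: float | None = None
    outer_radius_mm: float | None = None
    mu_per_cm: float = 0.0
    kinetics: tuple = ("blood", 0.0)

    def __post_init__(self):
        if self.mu_per_cm < 0:
            raise ValueError(f"region {self.name}: mu must be >= 0")
        if self.shape == "disc":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError(f"region {self.name}: disc needs radius > 0")
        elif self.shape == "annulus":
            ri, ro = self.inner_radius_mm, self.outer_radius_mm
            if ri is None or ro is None or ri <= 0 or ro <= ri:
                raise ValueError(f"region {self.name}: annulus needs 0 < inner < outer")
        elif self.shape != "full":
            raise ValueError(f"region {self.name}: unknown shape {self.shape!r}")
        if self.kinetics[0] not in ("blood", "tissue"):
            raise ValueError(f"region {self.name}: unknown kinetics {self.kinetics!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid plus ordered regions; later regions overwrite earlier ones.

    The canonical ordering is background < RV < LV < myocardium so the
    annulus boundary is deterministic.
    """

    grid: tuple[int, int]  # (nx, ny)
    voxel_size_mm: float
    regions: tuple[Region, ...]

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if not self.regions:
            raise ValueError("phantom needs at least one region")
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]


def voxel_centers(grid: tuple[int, int], voxel_size_mm: float):
    """Voxel-center coordinate images X, Y (mm), grid centered at the origin."""
    nx, ny = grid
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size_mm
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size_mm
    return np.meshgrid(x, y)  # shapes (ny, nx)


def rasterize_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize to a (label image, mu-map [1/cm]) pair.

    Voxel membership is center-in-region; later regions overwrite earlier
    ones.  A region extending beyond the grid is clipped with a warning.
    """
    X, Y = voxel_centers(spec.grid, spec.voxel_size_mm)
    labels = np.zeros(X.shape, dtype=np.int32)
    mu = np.zeros(X.shape, dtype=float)
    half_fov = min(spec.grid) * spec.voxel_size_mm / 2.0
    for idx, reg in enumerate(spec.regions):
        if reg.shape == "full":
            mask = np.ones(X.shape, dtype=bool)
        else:
            r2 = (X - reg.center_mm[0]) ** 2 + (Y - reg.center_mm[1]) ** 2
            if reg.shape == "disc":
                mask = r2 <= reg.radius_mm**2
                extent = np.hypot(*reg.center_mm) + reg.radius_mm
            else:
                mask = (r2 >= reg.inner_radius_mm**2) & (r2 <= reg.outer_radius_mm**2)
                extent = np.hypot(*reg.center_mm) + reg.outer_radius_mm
            if extent > half_fov + spec.voxel_size_mm:
                warnings.warn(
                    f"region {reg.name!r} extends beyond the grid and is clipped",
                    stacklevel=2,
                )
        labels[mask] = idx
        mu[mask] = reg.mu_per_cm
    return labels, mu


# ---------------------------------------------------------------------------
# Dynamic ground truth
# ---------------------------------------------------------------------------

@dataclass
class DynamicImageSeries:
    """Stack of per-frame activity-concentration images (kBq/mL)."""

    data: np.ndarray  # (n_frames, ny, nx)
    schedule: FrameSchedule
    voxel_size_mm: float
    decay_corrected: bool = False
    isotope_half_life_min: float = HALF_LIFE_C11_MIN

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != self.schedule.n_frames:
            raise ValueError("frame count does not match schedule")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data: np.ndarray, **kw) -> "DynamicImageSeries":
        out = replace(self, data=data)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def _region_curve(reg: Region, times_s: np.ndarray, input_params: InputFunctionParams,
                  decay_lambda_per_s: float) -> np.ndarray:
    """Regional non-decay-corrected activity on a time grid (seconds)."""
    from .kinetics import solve_1tcm_on_grid  # local import: avoids cycle at import time

    kind = reg.kinetics[0]
    if kind == "blood":
        shift = float(reg.kinetics[1]) if len(reg.kinetics) > 1 else 0.0
        c = evaluate_input_function(input_params, np.maximum(times_s + shift, 0.0))
    else:
        _, k1, k2 = reg.kinetics
        cp = evaluate_input_function(input_params, times_s)
        c = solve_1tcm_on_grid(k1, k2, times_s / 60.0, cp)
    if decay_lambda_per_s > 0:
        c = c * np.exp(-decay_lambda_per_s * times_s)
    return c


def make_dynamic_truth(
    spec: PhantomSpec,
    input_params: InputFunctionParams,
    schedule: FrameSchedule,
    *,
    decay: bool = True,
    half_life_min: float = HALF_LIFE_C11_MIN,
    fine_dt_s: float = 0.5,
) -> DynamicImageSeries:
    """Generate the ground-truth dynamic series.

    Each frame holds the time average over [start, start+duration] of the
    physically decaying regional activity (composite-Simpson integration on a
    ``fine_dt_s`` grid), i.e. frames are *not* decay corrected.  Blood regions
    follow the input curve (the RV may lead it); tissue regions follow the
    1-tissue-compartment solution driven by the (decay-free) input, with
    physical decay applied as a common multiplicative factor.
    """
    lam = np.log(2.0) / (half_life_min * 60.0) if decay else 0.0
    # Global fine grid; frame edges of the supported protocols are multiples
    # of fine_dt_s so Simpson panels align with frame boundaries.
    n_fine = int(round(schedule.total_duration / fine_dt_s))
    times = np.linspace(0.0, schedule.total_duration, n_fine + 1)

    labels, _ = rasterize_phantom(spec)
    ny, nx = labels.shape
    frames = np.zeros((schedule.n_frames, ny, nx))

    for idx, reg in enumerate(spec.regions):
        mask = labels == idx
        if not np.any(mask):
            continue
        curve = _region_curve(reg, times, input_params, lam)
        for f in range(schedule.n_frames):
            i0 = int(round(schedule.starts[f] / fine_dt_s))
            i1 = int(round(schedule.ends[f] / fine_dt_s))
            i0, i1 = min(i0, n_fine), min(i1, n_fine)
            seg_t, seg_c = times[i0:i1 + 1], curve[i0:i1 + 1]
            if seg_t.size < 3:
                avg = float(np.trapezoid(seg_c, seg_t) / (seg_t[-1] - seg_t[0]))
            else:
                avg = float(simpson(seg_c, x=seg_t) / (seg_t[-1] - seg_t[0]))
            frames[f][mask] = avg

    return DynamicImageSeries(
        data=frames,
        schedule=schedule,
        voxel_size_mm=spec.voxel_size_mm,
        decay_corrected=False,
        isotope_half_life_min=half_life_min,
    )


# ---------------------------------------------------------------------------
# Default cardiac phantom
# ---------------------------------------------------------------------------

#: Attenuation of water at 511 keV, used for all soft-tissue regions.
MU_WATER_PER_CM = 0.096


def cardiac_phantom(
    nx: int = 128,
    ny: int = 128,
    voxel_size_mm: float = 2.0,
    *,
    myo_k1: float = 0.8,
    myo_k2: float = 0.2,
    background_k1: float = 0.1,
    background_k2: float = 0.05,
    rv_lead_s: float = 4.0,
) -> PhantomSpec:
    """Default 2D cardiac cross-section.

    LV blood disc (r = 11 mm) with a 8 mm-thick myocardial annulus, an RV
    blood disc beside it, inside a water-equivalent body disc with low
    background uptake.  Anatomy is fixed in mm so it is grid-independent as
    long as the field of view is at least ~110 mm.  The RV blood curve leads
    the LV input by ``rv_lead_s`` to mimic right-heart transit.
    """
    fov = min(nx, ny) * voxel_size_mm
    body_r = 0.46 * fov
    regions = (
        Region("air", "full", mu_per_cm=0.0, kinetics=("tissue", 0.0, 0.0)),
        Region("body", "disc", (0.0, 0.0), radius_mm=body_r,
               mu_per_cm=MU_WATER_PER_CM,
               kinetics=("tissue", background_k1, background_k2)),
        Region("rv_blood", "disc", (17.0, 4.0), radius_mm=9.0,
               mu_per_cm=MU_WATER_PER_CM, kinetics=("blood", rv_lead_s)),
        Region("lv_blood", "disc", (-12.0, 0.0), radius_mm=11.0,
               mu_per_cm=MU_WATER_PER_CM, kinetics=("blood", 0.0)),
        Region("myocardium", "annulus", (-12.0, 0.0),
               inner_radius_mm=11.0, outer_radius_mm=19.0,
               mu_per_cm=MU_WATER_PER_CM, kinetics=("tissue", myo_k1, myo_k2)),
    )
    return PhantomSpec(grid=(nx, ny), voxel_size_mm=voxel_size_mm, regions=regions)
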