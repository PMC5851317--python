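"""FBP and the ordinary-Poisson OSEM family (OSEM / TOF / TOF+PSF).

The iterative update, cycling angular subsets S_q within each iteration, is

    f_j <- f_j / (sum_{i in S_q} A_ij) * sum_{i in S_q} A_ij * p_i /
           (sum_l A_il f_l + r_i + s_i)

with randoms r and scatter s kept inside the denominator (ordinary-Poisson
form) rather than pre-subtracted; images stay nonnegative.  For FBP the
prompts are pre-corrected — (p - r - s) divided by attenuation and
normalization — ramp-filtered per angle (optionally Hann-apodized) and
backprojected; FBP images may go negative.

Image-quality bookkeeping uses EM-equivalent iterations = iterations x
subsets, which puts runs with different subset counts on one convergence
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import HALF_LIFE_C11_MIN
from .projection import SinogramSet, SystemOperator, make_subsets

__all__ = [
    "ReconConfig",
    "ReconResult",
    "osem_reconstruct",
    "fbp_reconstruct",
    "post_filter",
    "to_activity_concentration",
    "frame_decay_factor",
    "decay_correction_factor",
    "default_recon_configs",
    "EPS",
]

#: Floor on EM denominators and sensitivities; voxels with (near-)zero
#: sensitivity are frozen at zero.
EPS = 1e-12

METHODS = ("FBP", "OSEM", "TOF", "TPSF")


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction settings for one method.

    Defaults mirror the clinical protocol: OSEM 20 iterations x 10 subsets
    (EM-equivalent 200) with a 6.5 mm post-filter; TOF and TPSF 10 x 10
    (EM-equivalent 100) with a 5.0 mm post-filter; FBP with a Hann-apodized
    ramp.
    """

    method: str = "OSEM"
    n_iterations: int = 20
    n_subsets: int = 10
    postfilter_fwhm_mm: float = 6.5
    fbp_apodization: str = "hann"  # "ramp" | "hann"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method != "FBP" and self.n_iterations < 1:
            raise ValueError("iterative methods need n_iterations >= 1")
        if self.postfilter_fwhm_mm < 0:
            raise ValueError("post-filter FWHM must be >= 0")
        if self.fbp_apodization not in ("ramp", "hann"):
            raise ValueError("fbp_apodization must be 'ramp' or 'hann'")

    @property
    def em_equivalent(self) -> int:
        return self.n_iterations * self.n_subsets


def default_recon_configs() -> dict[str, ReconConfig]:
    return {
        "FBP": ReconConfig("FBP", n_iterations=1, n_subsets=1,
                           postfilter_fwhm_mm=0.0, fbp_apodization="hann"),
        "OSEM": ReconConfig("OSEM", 20, 10, 6.5),
        "TOF": ReconConfig("TOF", 10, 10, 5.0),
        "TPSF": ReconConfig("TPSF", 10, 10, 5.0),
    }


@dataclass
class ReconResult:
    image: np.ndarray
    config: ReconConfig
    snapshots: list = field(default_factory=list)  # [(em_equivalent, image), ...]


def _check_method_operator(config: ReconConfig, operator: SystemOperator):
    if config.method in ("TOF", "TPSF") and not operator.has_tof:
        raise ValueError(f"{config.method} requires a TOF-enabled operator")
    if config.method == "TPSF" and (operator.psf is None or operator.psf.fwhm_mm <= 0):
        raise ValueError("TPSF requires PSF enabled on the operator")


def osem_reconstruct(
    data: SinogramSet,
    operator: SystemOperator,
    config: ReconConfig,
    initial: np.ndarray | None = None,
    keep_snapshots: bool = False,
) -> ReconResult:
    """Ordinary-Poisson OSEM; with ``n_subsets == 1`` this is plain MLEM.

    ``keep_snapshots`` stores the image after every full iteration together
    with its EM-equivalent iteration number, for convergence analyses.
    """
    _check_method_operator(config, operator)
    p, r, s = data.prompts, data.randoms, data.scatter
    if p.shape != operator.sinogram_shape:
        raise ValueError(f"sinogram shape {p.shape} != operator {operator.sinogram_shape}")
    nx, ny = operator.grid
    if initial is None:
        f = np.ones((ny, nx))
    else:
        f = np.asarray(initial, dtype=float).copy()
        if np.any(f < 0):
            raise ValueError("initial image must be nonnegative")

    partition = make_subsets(operator.n_angles, config.n_subsets)
    sens = [operator.sensitivity(S) for S in partition.subsets]
    alive = [sv > EPS for sv in sens]

    snapshots = []
    for k in range(config.n_iterations):
        for q, S in enumerate(partition.subsets):
            idx = np.asarray(S)
            proj = operator.forward_subset(f, S)
            denom = proj + r[idx] + s[idx]
            ratio = p[idx] / np.maximum(denom, EPS)
            update = operator.back_subset(ratio, S)
            f = np.where(alive[q], f * update / np.maximum(sens[q], EPS), 0.0)
        if keep_snapshots:
            snapshots.append(((k + 1) * config.n_subsets, f.copy()))
    return ReconResult(image=f, config=config, snapshots=snapshots)


def _ramp_filter_profiles(profiles: np.ndarray, bin_width_mm: float,
                          apodization: str) -> np.ndarray:
    """Ramp-filter each angular profile (rows) via zero-padded FFT."""
    n = profiles.shape[1]
    npad = int(2 ** np.ceil(np.log2(2 * n)))
    freqs = np.fft.rfftfreq(npad, d=bin_width_mm)
    H = np.abs(freqs)
    if apodization == "hann":
        f_ny = 0.5 / bin_width_mm
        H = H * 0.5 * (1.0 + np.cos(np.pi * freqs / f_ny))
    spec = np.fft.rfft(profiles, n=npad, axis=1)
    filtered = np.fft.irfft(spec * H[None, :], n=npad, axis=1)
    return filtered[:, :n]


def fbp_reconstruct(
    data: SinogramSet,
    operator: SystemOperator,
    config: ReconConfig | None = None,
) -> ReconResult:
    """Filtered backprojection with direct randoms/scatter pre-subtraction.

    TOF sinograms are summed over TOF bins first (FBP does not use TOF); the
    detector PSF factor is not modelled.  Linear in the prompts; output may
    contain negative values.
    """
    if config is None:
        config = default_recon_configs()["FBP"]
    nt = data.summed_over_tof()
    corrected = (nt.prompts - nt.randoms - nt.scatter) / (
        operator.attenuation * operator.normalization)
    filtered = _ramp_filter_profiles(corrected, operator.bin_width_mm,
                                     config.fbp_apodization)
    image = (np.pi / operator.n_angles) / operator.voxel_size_mm \
        * operator.geometric_back(filtered)
    return ReconResult(image=image, config=config)


def post_filter(image: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian post-filter; sigma = FWHM/2.3548 converted to voxels.

    ``fwhm_mm == 0`` returns the image unchanged.  Reflective boundary
    handling preserves the image sum.
    """
    if fwhm_mm < 0:
        raise ValueError("post-filter FWHM must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(image).copy()
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect",
                           truncate=8.0)


def decay_correction_factor(t_s: float, half_life_min: float = HALF_LIFE_C11_MIN) -> float:
    """Instantaneous decay-correction factor 2^(t/T1/2) back to injection."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    return float(2.0 ** (t_s / (half_life_min * 60.0)))


def frame_decay_factor(start_s: float, duration_s: float,
                       half_life_min: float = HALF_LIFE_C11_MIN) -> float:
    """Frame-averaged decay factor (1/T) * int_start^start+T exp(-lambda t) dt."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    if duration_s <= 0:
        raise ValueError("frame duration must be positive")
    lam = np.log(2.0) / (half_life_min * 60.0)
    return float((np.exp(-lam * start_s) - np.exp(-lam * (start_s + duration_s)))
                 / (lam * duration_s))


def to_activity_concentration(
    image: np.ndarray,
    frame: tuple[float, float],
    half_life_min: float = HALF_LIFE_C11_MIN,
    calibration: float = 1.0,
) -> np.ndarray:
    """Convert a reconstructed count-scale frame to decay-corrected kBq/mL.

    Divides by the frame duration and the frame-averaged physical decay
    factor (decay referenced to the injection time), then applies the scanner
    calibration scale.
    """
    start_s, duration_s = frame
    dec = frame_decay_factor(start_s, duration_s, half_life_min)
    return np.asarray(image, dtype=float) * calibration / (duration_s * dec)
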