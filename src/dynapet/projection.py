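"""Factored 2D parallel-beam system model with TOF, PSF and attenuation.

The system response A is a product of per-LOR normalization and attenuation
factors, an optional radial Gaussian detector point-spread factor applied in
sinogram space, and a geometric projection matrix.  With time-of-flight
enabled, each line-of-response contribution is additionally distributed over
TOF bins by a Gaussian positional kernel along the LOR, making the sinogram
three-dimensional (angle, radial, tof).

The geometric matrix uses pixel-driven linear-interpolation splatting: each
voxel center projects to a continuous radial coordinate at every angle and
its value (weighted by the voxel size, so projections approximate line
integrals in value*mm) is shared between the two neighbouring radial bins.
Forward and back projection are realized as one sparse matrix and its
transpose, so the pair is adjoint to machine precision by construction —
which the expectation-maximization update requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import convolve1d

__all__ = [
    "ProjectionGeometry",
    "TOFConfig",
    "PSFConfig",
    "SystemOperator",
    "SinogramSet",
    "SubsetPartition",
    "build_system_operator",
    "forward_project",
    "back_project",
    "simulate_counts",
    "make_subsets",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam geometry: ``n_angles`` over [0, 180) degrees; radial bin
    width defaults to the voxel size."""

    n_angles: int = 180
    n_radial: int | None = None
    bin_width_mm: float | None = None


@dataclass(frozen=True)
class TOFConfig:
    """TOF binning along the LOR.  The default 80 mm FWHM kernel corresponds
    to roughly 530 ps coincidence timing resolution."""

    n_bins: int = 13
    bin_width_mm: float = 30.0
    kernel_fwhm_mm: float = 80.0


@dataclass(frozen=True)
class PSFConfig:
    """Shift-invariant radial Gaussian detector response in sinogram space."""

    fwhm_mm: float = 4.0


@dataclass
class SinogramSet:
    """Measured prompts with randoms/scatter expectations for one frame.

    Shapes are (n_angles, n_radial) or (n_angles, n_radial, n_tof).
    """

    prompts: np.ndarray
    randoms: np.ndarray
    scatter: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.prompts = np.asarray(self.prompts, dtype=float)
        self.randoms = np.asarray(self.randoms, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if not (self.prompts.shape == self.randoms.shape == self.scatter.shape):
            raise ValueError("prompts, randoms and scatter shapes must match")
        if np.any(self.prompts < 0) or np.any(self.randoms < 0) or np.any(self.scatter < 0):
            raise ValueError("sinogram entries must be nonnegative")

    @property
    def has_tof(self) -> bool:
        return self.prompts.ndim == 3

    def summed_over_tof(self) -> "SinogramSet":
        if not self.has_tof:
            return self
        return SinogramSet(self.prompts.sum(axis=2), self.randoms.sum(axis=2),
                           self.scatter.sum(axis=2), self.frame_index)


@dataclass(frozen=True)
class SubsetPartition:
    """Interleaved angular subsets: subset q holds angles with index ≡ q
    (mod n_subsets); disjoint, exhaustive, sizes differ by at most 1."""

    subsets: tuple
    n_subsets: int


def make_subsets(n_angles: int, n_subsets: int) -> SubsetPartition:
    if not (1 <= n_subsets <= n_angles):
        raise ValueError(f"n_subsets must be in [1, {n_angles}], got {n_subsets}")
    subsets = tuple(np.arange(q, n_angles, n_subsets) for q in range(n_subsets))
    return SubsetPartition(subsets=subsets, n_subsets=n_subsets)


def _geometry_matrices(grid, voxel_size_mm, geom: ProjectionGeometry,
                       tof: TOFConfig | None):
    """Sparse geometric matrix (rows angle-major, radial next, TOF last) and,
    when TOF is enabled, also the plain non-TOF matrix."""
    nx, ny = grid
    n_radial = geom.n_radial or nx
    bin_w = geom.bin_width_mm or voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size_mm
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size_mm
    X, Y = np.meshgrid(x, y)
    xs, ys = X.ravel(), Y.ravel()
    npix = xs.size
    angles = np.pi * np.arange(geom.n_angles) / geom.n_angles

    if tof is not None:
        centers = (np.arange(tof.n_bins) - (tof.n_bins - 1) / 2.0) * tof.bin_width_mm
        sigma = tof.kernel_fwhm_mm * FWHM_TO_SIGMA

    rows, cols, vals = [], [], []
    rows_nt, cols_nt, vals_nt = [], [], []
    for a, th in enumerate(angles):
        s = xs * np.cos(th) + ys * np.sin(th)
        sidx = s / bin_w + (n_radial - 1) / 2.0
        i0 = np.floor(sidx).astype(np.int64)
        w1 = sidx - i0
        for ioff, wgt in ((0, 1.0 - w1), (1, w1)):
            b = i0 + ioff
            ok = (b >= 0) & (b < n_radial) & (wgt > 0)
            pix = np.flatnonzero(ok)
            bins = b[ok]
            wv = wgt[ok] * voxel_size_mm
            base = a * n_radial + bins
            rows_nt.append(base)
            cols_nt.append(pix)
            vals_nt.append(wv)
            if tof is not None:
                u = -xs[pix] * np.sin(th) + ys[pix] * np.cos(th)
                wt = np.exp(-0.5 * ((u[:, None] - centers[None, :]) / sigma) ** 2)
                wt /= wt.sum(axis=1, keepdims=True)
                # drop negligible bins, renormalize so TOF marginalization
                # over bins is exact
                keep = wt > 1e-3 * wt.max(axis=1, keepdims=True)
                wt = np.where(keep, wt, 0.0)
                wt /= wt.sum(axis=1, keepdims=True)
                pj, tj = np.nonzero(wt)
                rows.append(base[pj] * tof.n_bins + tj)
                cols.append(pix[pj])
                vals.append(wv[pj] * wt[pj, tj])

    def build(r, c, v, nrows):
        return sp.csr_matrix(
            (np.concatenate(v), (np.concatenate(r), np.concatenate(c))),
            shape=(nrows, npix),
        )

    g_geo = build(rows_nt, cols_nt, vals_nt, geom.n_angles * n_radial)
    g_tof = None
    if tof is not None:
        g_tof = build(rows, cols, vals, geom.n_angles * n_radial * tof.n_bins)
    return g_geo, g_tof, n_radial, bin_w


class SystemOperator:
    """Factored system response with exact forward/adjoint pair."""

    def __init__(self, grid, voxel_size_mm, geometry, tof, psf,
                 attenuation, normalization, g_geo, g_tof, n_radial, bin_width_mm):
        self.grid = grid                      # (nx, ny)
        self.voxel_size_mm = voxel_size_mm
        self.geometry = geometry
        self.tof = tof
        self.psf = psf
        self.attenuation = attenuation        # (n_angles, n_radial), in (0, 1]
        self.normalization = normalization    # (n_angles, n_radial), > 0
        self._g_geo = g_geo
        self._g_tof = g_tof
        self.n_radial = n_radial
        self.bin_width_mm = bin_width_mm
        self._subset_cache: dict = {}
        if psf is not None and psf.fwhm_mm > 0:
            sig = psf.fwhm_mm * FWHM_TO_SIGMA / bin_width_mm
            rad = max(int(np.ceil(4 * sig)), 1)
            k = np.exp(-0.5 * (np.arange(-rad, rad + 1) / sig) ** 2)
            self._psf_kernel = k / k.sum()
        else:
            self._psf_kernel = None

    # -- basic properties ---------------------------------------------------
    @property
    def n_angles(self) -> int:
        return self.geometry.n_angles

    @property
    def has_tof(self) -> bool:
        return self._g_tof is not None

    @property
    def sinogram_shape(self) -> tuple:
        if self.has_tof:
            return (self.n_angles, self.n_radial, self.tof.n_bins)
        return (self.n_angles, self.n_radial)

    def _matrix(self):
        return self._g_tof if self.has_tof else self._g_geo

    def _factors(self):
        return self.attenuation * self.normalization

    def _apply_psf(self, sino):
        if self._psf_kernel is None:
            return sino
        # radial axis is 1; zero boundary keeps the operation self-adjoint
        return convolve1d(sino, self._psf_kernel, axis=1, mode="constant", cval=0.0)

    # -- full forward / back ------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        nx, ny = self.grid
        if image.shape != (ny, nx):
            raise ValueError(f"image shape {image.shape} does not match grid {(ny, nx)}")
        g = (self._matrix() @ image.ravel()).reshape(self.sinogram_shape)
        g = self._apply_psf(g)
        f = self._factors()
        return g * (f[..., None] if self.has_tof else f)

    def back(self, sinogram: np.ndarray) -> np.ndarray:
        sinogram = np.asarray(sinogram, dtype=float)
        if sinogram.shape != self.sinogram_shape:
            raise ValueError(f"sinogram shape {sinogram.shape} != {self.sinogram_shape}")
        f = self._factors()
        y = sinogram * (f[..., None] if self.has_tof else f)
        y = self._apply_psf(y)
        nx, ny = self.grid
        return (self._matrix().T @ y.ravel()).reshape(ny, nx)

    # -- subset forward / back ---------------------------------------------
    def _subset_matrix(self, angles: tuple):
        key = angles
        if key not in self._subset_cache:
            idx = np.asarray(angles)
            if self.has_tof:
                block = self.n_radial * self.tof.n_bins
            else:
                block = self.n_radial
            rows = (idx[:, None] * block + np.arange(block)[None, :]).ravel()
            self._subset_cache[key] = self._matrix()[rows]
        return self._subset_cache[key]

    def _subset_shape(self, n_sub_angles):
        if self.has_tof:
            return (n_sub_angles, self.n_radial, self.tof.n_bins)
        return (n_sub_angles, self.n_radial)

    def forward_subset(self, image, angle_indices) -> np.ndarray:
        angles = tuple(int(a) for a in angle_indices)
        m = self._subset_matrix(angles)
        g = (m @ np.asarray(image, dtype=float).ravel()).reshape(self._subset_shape(len(angles)))
        g = self._apply_psf(g)
        f = self._factors()[list(angles)]
        return g * (f[..., None] if self.has_tof else f)

    def back_subset(self, sino_subset, angle_indices) -> np.ndarray:
        angles = tuple(int(a) for a in angle_indices)
        f = self._factors()[list(angles)]
        y = np.asarray(sino_subset, dtype=float) * (f[..., None] if self.has_tof else f)
        y = self._apply_psf(y)
        m = self._subset_matrix(angles)
        nx, ny = self.grid
        return (m.T @ y.ravel()).reshape(ny, nx)

    def sensitivity(self, angle_indices) -> np.ndarray:
        """Back projection of a unit sinogram over the given angles."""
        angles = tuple(int(a) for a in angle_indices)
        ones = np.ones(self._subset_shape(len(angles)))
        return self.back_subset(ones, angles)

    # -- geometric-only helpers (FBP, attenuation) --------------------------
    def geometric_forward(self, image: np.ndarray) -> np.ndarray:
        return (self._g_geo @ np.asarray(image, dtype=float).ravel()).reshape(
            self.n_angles, self.n_radial)

    def geometric_back(self, sinogram: np.ndarray) -> np.ndarray:
        nx, ny = self.grid
        return (self._g_geo.T @ np.asarray(sinogram, dtype=float).ravel()).reshape(ny, nx)


def build_system_operator(
    mu_map: np.ndarray,
    voxel_size_mm: float,
    geometry: ProjectionGeometry = ProjectionGeometry(),
    tof: TOFConfig | None = None,
    psf: PSFConfig | None = None,
    normalization: np.ndarray | None = None,
) -> SystemOperator:
    """Build the factored operator for a given attenuation map (1/cm).

    Attenuation factors are ``exp(-line integral of mu)`` per LOR, computed
    with the same geometric projector (mu converted to 1/mm).  Normalization
    defaults to unity everywhere.
    """
    mu_map = np.asarray(mu_map, dtype=float)
    if np.any(mu_map < 0):
        raise ValueError("attenuation map must be nonnegative")
    ny, nx = mu_map.shape
    g_geo, g_tof, n_radial, bin_w = _geometry_matrices((nx, ny), voxel_size_mm,
                                                       geometry, tof)
    line_int = (g_geo @ (mu_map.ravel() / 10.0)).reshape(geometry.n_angles, n_radial)
    attenuation = np.exp(-line_int)
    if normalization is None:
        normalization = np.ones_like(attenuation)
    else:
        normalization = np.asarray(normalization, dtype=float)
        if np.any(normalization <= 0):
            raise ValueError("normalization factors must be positive")
    return SystemOperator((nx, ny), voxel_size_mm, geometry, tof, psf,
                          attenuation, normalization, g_geo, g_tof, n_radial, bin_w)


def forward_project(image: np.ndarray, operator: SystemOperator) -> np.ndarray:
    """Expected (noise-free) sinogram of an activity image."""
    return operator.forward(image)


def back_project(sinogram: np.ndarray, operator: SystemOperator) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`."""
    return operator.back(sinogram)


def simulate_counts(
    expected_trues: np.ndarray,
    randoms_fraction: float,
    scatter_fraction: float,
    seed,
    frame_index: int = 0,
    scatter_fwhm_mm: float = 50.0,
    bin_width_mm: float = 2.0,
) -> SinogramSet:
    """Poisson prompts with additive randoms/scatter expectations.

    Randoms are uniform with per-bin expectation ``randoms_fraction *
    mean(trues)``; scatter is a broad radial Gaussian blur of the trues
    rescaled so total scatter = ``scatter_fraction * total trues``.
    """
    trues = np.asarray(expected_trues, dtype=float)
    if np.any(trues < 0):
        raise ValueError("expected trues must be nonnegative")
    if randoms_fraction < 0 or scatter_fraction < 0:
        raise ValueError("randoms/scatter fractions must be nonnegative")
    randoms = np.full_like(trues, randoms_fraction * trues.mean())
    if scatter_fraction > 0 and trues.sum() > 0:
        sig = scatter_fwhm_mm * FWHM_TO_SIGMA / bin_width_mm
        from scipy.ndimage import gaussian_filter1d

        smooth = gaussian_filter1d(trues, sig, axis=1, mode="constant", cval=0.0)
        total = smooth.sum()
        scatter = smooth * (scatter_fraction * trues.sum() / total) if total > 0 else np.zeros_like(trues)
    else:
        scatter = np.zeros_like(trues)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prompts = rng.poisson(trues + randoms + scatter).astype(float)
    return SinogramSet(prompts=prompts, randoms=randoms, scatter=scatter,
                       frame_index=frame_index)
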