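"""Synthetic signals and smoothed Gaussian noise for simulation studies.

Everything needed to exercise the confidence-region pipeline without any
external data: binary circle/square templates and linear ramps for the
target functions, plus stationary smoothed (optionally cross-correlated,
optionally heavy-tailed) noise with unit pointwise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fields import GridSpec, ScalarField, as_values

__all__ = [
    "FWHM_SIGMA_FACTOR",
    "SignalSpec",
    "NoiseSpec",
    "SyntheticDataset",
    "fwhm_to_sigma",
    "smoothing_kernel",
    "gaussian_smooth",
    "make_signal",
    "generate_noise",
    "generate_dataset",
]

#: Conversion between the full width at half maximum of a Gaussian kernel
#: and its standard deviation: sigma = FWHM * FWHM_SIGMA_FACTOR.
FWHM_SIGMA_FACTOR = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Kernel standard deviation (pixels) for a given FWHM (pixels)."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    return float(fwhm) * FWHM_SIGMA_FACTOR


def smoothing_kernel(fwhm: float) -> np.ndarray:
    """Normalised 1-D Gaussian kernel used for all smoothing in this package.

    The kernel is truncated at four standard deviations (radius
    ``int(4 * sigma + 0.5)``), matching :func:`scipy.ndimage.gaussian_filter1d`,
    and normalised to sum to one.  ``fwhm = 0`` gives the identity kernel.
    """
    sigma = fwhm_to_sigma(fwhm)
    if sigma == 0.0:
        return np.ones(1)
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(fld: ScalarField | np.ndarray, fwhm: float) -> ScalarField:
    """Convolve a field with a normalised isotropic Gaussian kernel.

    Edges are handled by reflection, which preserves constant fields.
    ``fwhm = 0`` returns the input unchanged.
    """
    v = as_values(fld)
    sigma = fwhm_to_sigma(fwhm)
    if sigma == 0.0:
        return ScalarField(v.copy())
    return ScalarField(ndimage.gaussian_filter(v, sigma, mode="reflect", truncate=4.0))


@dataclass(frozen=True)
class SignalSpec:
    """Geometry of a synthetic target function.

    ``kind`` selects between a smoothed binary disc (``"circle"``), a
    smoothed binary square (``"square"``) and a linear ramp (``"ramp"``).
    Circle/square templates for the two conditions are placed symmetrically
    about the grid centre, ``separation`` pixels apart along the second
    axis; ramps vary along the second axis (condition 0) or the first axis
    (condition 1).

    Ramps are exactly linear: no template is built and no smoothing is
    applied (a symmetric kernel leaves the interior of a linear field
    unchanged anyway, and skipping it keeps the gradient exact up to the
    image edge).
    """

    kind: str
    magnitude: float = 3.0
    separation: float = 20.0
    gradient: float = 1.0 / 50.0
    ramp_offset: float = 0.0
    smoothing_fwhm: float = 5.0
    radius: float = 30.0
    side: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "square", "ramp"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be non-negative")

    def scaled(self, factor: float) -> "SignalSpec":
        """Spec with ``magnitude``, ``gradient`` and ``ramp_offset`` scaled."""
        return replace(
            self,
            magnitude=self.magnitude * factor,
            gradient=self.gradient * factor,
            ramp_offset=self.ramp_offset * factor,
        )


def make_signal(spec: SignalSpec, grid: GridSpec, condition: int = 0) -> ScalarField:
    """Build the target function for one study condition.

    Circle and square templates are binary-valued {0, magnitude} images which
    are then Gaussian-smoothed with ``spec.smoothing_fwhm``.  ``condition``
    is 0-based; conditions 0 and 1 are offset by ``-separation/2`` and
    ``+separation/2`` pixels along the last grid axis.

    Raises
    ------
    ValueError
        If the template geometry places the shape fully outside the grid.
    """
    if grid.ndim != 2:
        raise ValueError("make_signal requires a 2-D grid")
    if condition < 0:
        raise ValueError("condition index must be >= 0")
    ny, nx = grid.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(np.float64)

    if spec.kind == "ramp":
        coord = cols if condition % 2 == 0 else rows
        return ScalarField(spec.ramp_offset + spec.gradient * coord, grid)

    offset = (-0.5 + (condition % 2)) * spec.separation
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0 + offset
    if spec.kind == "circle":
        template = (rows - cy) ** 2 + (cols - cx) ** 2 <= spec.radius**2
    else:
        template = (np.abs(rows - cy) <= spec.side / 2.0) & (np.abs(cols - cx) <= spec.side / 2.0)
    if not template.any():
        raise ValueError("signal template lies entirely outside the grid")
    return gaussian_smooth(ScalarField(spec.magnitude * template.astype(np.float64), grid), spec.smoothing_fwhm)


@dataclass(frozen=True)
class NoiseSpec:
    """Distributional settings for the per-observation noise fields.

    White noise is drawn per pixel, optionally cross-correlated between the
    two study conditions (``epsilon_2 = rho * epsilon_1 +
    sqrt(1 - rho^2) * epsilon_perp`` before smoothing), smoothed with an
    isotropic Gaussian kernel of the given FWHM, and, when ``restandardise``
    is set (the default), divided by the theoretical pointwise standard
    deviation of the smoothed white field so the marginal variance is one.

    ``distribution = "heavy_tailed"`` replaces the Gaussian white noise with
    Student-t white noise (``df`` degrees of freedom, df > 2) rescaled to
    unit variance before smoothing.
    """

    fwhm: float = 3.0
    cross_correlation: float = 0.0
    distribution: str = "gaussian"
    df: float = 3.0
    restandardise: bool = True

    def __post_init__(self) -> None:
        if abs(self.cross_correlation) > 1:
            raise ValueError("|cross_correlation| must be <= 1")
        if self.distribution not in ("gaussian", "heavy_tailed"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")
        if self.distribution == "heavy_tailed" and self.df <= 2:
            raise ValueError("heavy-tailed noise requires df > 2 for a finite variance")
        if self.fwhm < 0:
            raise ValueError("fwhm must be non-negative")


def _crop_smoothing_matrix(extent: int, pad: int, kernel: np.ndarray) -> np.ndarray:
    """Dense operator mapping a padded 1-D axis to its smoothed, cropped core."""
    radius = (len(kernel) - 1) // 2
    padded = extent + 2 * pad
    s = np.zeros((extent, padded))
    for i in range(extent):
        centre = i + pad
        lo = centre - radius
        for j, kj in enumerate(kernel):
            jj = lo + j
            if 0 <= jj < padded:
                s[i, jj] += kj
    return s


def _white_noise(rng: np.random.Generator, shape: tuple[int, ...], spec: NoiseSpec, dtype) -> np.ndarray:
    if spec.distribution == "gaussian":
        return rng.standard_normal(shape, dtype=dtype)
    scale = np.sqrt((spec.df - 2.0) / spec.df)
    return (rng.standard_t(spec.df, size=shape) * scale).astype(dtype)


def generate_noise(
    n_obs: int,
    n_cond: int,
    grid: GridSpec,
    spec: NoiseSpec,
    rng: np.random.Generator | int | None = None,
    dtype=np.float64,
) -> np.ndarray:
    """Draw per-condition stacks of smoothed noise fields.

    Returns an array of shape ``(n_cond, n_obs, *grid.shape)``.  Noise is
    generated on a grid padded by the kernel radius per side, smoothed, then
    cropped, so every returned pixel sees the full kernel and the field is
    stationary (no edge-variance artefacts).  Fixed ``rng`` seed gives
    bit-identical output.

    Cross-condition correlation is induced by mixing the white fields before
    smoothing and is only supported for ``n_cond == 2``.
    """
    if n_obs < 2:
        raise ValueError("need at least two observations")
    if n_cond < 1:
        raise ValueError("need at least one condition")
    rho = spec.cross_correlation
    if rho != 0.0 and n_cond != 2:
        raise ValueError("cross-correlated noise is defined for exactly two conditions")
    rng = np.random.default_rng(rng)

    kernel = smoothing_kernel(spec.fwhm)
    pad = (len(kernel) - 1) // 2
    padded_shape = tuple(s + 2 * pad for s in grid.shape)

    white = _white_noise(rng, (n_cond, n_obs) + padded_shape, spec, dtype)
    if rho != 0.0:
        mixed = rho * white[0] + np.sqrt(1.0 - rho * rho) * white[1]
        white[1] = mixed.astype(dtype)

    if pad == 0:
        out = white
    else:
        mats = [_crop_smoothing_matrix(s, pad, kernel).astype(dtype) for s in grid.shape]
        if grid.ndim == 2:
            s0, s1 = mats
            # separable smoothing as two GEMMs: columns first, then rows
            flat = white.reshape(-1, padded_shape[1])
            tmp = (flat @ s1.T).reshape(n_cond * n_obs, padded_shape[0], grid.shape[1])
            out = np.matmul(s0, tmp).reshape((n_cond, n_obs) + grid.shape)
        else:
            out = white
            for axis, mat in enumerate(mats):
                out = np.moveaxis(np.tensordot(out, mat, axes=([2 + axis], [1])), -1, 2 + axis)
            out = np.ascontiguousarray(out, dtype=dtype)

    if spec.restandardise:
        sd = float(np.sum(kernel**2)) ** (grid.ndim / 2.0)
        out /= np.asarray(sd, dtype=out.dtype)  # keep the stack's dtype
    return out


@dataclass(frozen=True)
class SyntheticDataset:
    """Observations plus the ground truth needed for coverage checking."""

    responses: np.ndarray  # (n_cond, n_obs, *grid.shape)
    signals: tuple[ScalarField, ...]
    threshold: float
    true_mask: np.ndarray  # bool, lattice conjunction set of the true signals
    true_boundary: list = field(repr=False, default_factory=list)

    @property
    def n_cond(self) -> int:
        return self.responses.shape[0]

    @property
    def n_obs(self) -> int:
        return self.responses.shape[1]


def generate_dataset(
    signals: list[ScalarField],
    noise: np.ndarray,
    threshold: float,
) -> SyntheticDataset:
    """Combine true signals with noise stacks into observed responses.

    ``responses[i, l] = signals[i] + noise[i, l]``.  Also returns the true
    lattice conjunction mask ``{min_i mu_i >= c}`` and its sub-pixel boundary
    (linear interpolation of ``min_i mu_i - c`` along lattice edges), which
    the coverage harness uses for inclusion checking.
    """
    from .excursion_geometry import extract_zero_boundary

    if len(signals) != noise.shape[0]:
        raise ValueError("one noise stack per signal is required")
    grid = signals[0].grid
    for s in signals:
        if s.grid.shape != grid.shape:
            raise ValueError("all signals must share a grid")
    if noise.shape[2:] != grid.shape:
        raise ValueError("noise fields must match the signal grid")

    mu = np.stack([s.values for s in signals])
    responses = mu[:, None] + noise
    margin = mu.min(axis=0) - threshold
    return SyntheticDataset(
        responses=responses,
        signals=tuple(signals),
        threshold=float(threshold),
        true_mask=margin >= 0,
        true_boundary=extract_zero_boundary(margin),
    )
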