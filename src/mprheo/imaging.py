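"""Synthetic multiplane image formation.

Renders the tiled camera frames a multiplane (diffraction-grating) microscope
produces: one 2D integer image per time point containing a grid of sub-images,
each sub-image conjugate to an object plane at ``z = n * plane_spacing`` for
integer plane index ``n``.

Image model
-----------
The bead is rendered as a projected disk of the bead diameter convolved with
an isotropic Gaussian whose width grows with defocus,

    sigma(n) = sqrt(psf_sigma0**2 + (defocus_slope * |z - n dz|)**2).

The convolution of a uniform disk with a Gaussian has the closed form
``1 - Q1(rho/sigma, R/sigma)`` (Marcum Q), evaluated here through the
non-central chi-squared CDF.  The amplitude is fixed by requiring the
in-focus peak to equal ``contrast``; because convolution conserves the
integral, the background-subtracted signal sum is then identical in every
plane while the peak height falls as the blur grows — which is all the
sharpness-based axial localisation needs: a unimodal, symmetric
sharpness-versus-defocus curve.  Real transmission images show diffraction
rings this model omits.

Shot noise, when enabled, is Poisson per pixel on the expected count
(background + signal); output frames are integer-quantised either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import ncx2

from .errors import InvalidParameterError, OutOfBoundsError
from .trap_dynamics import Trajectory

__all__ = [
    "OpticalConfig",
    "RawFrame",
    "render_frame",
    "render_trajectory_frames",
    "render_zscan",
]


def _default_layout(n_planes: int) -> tuple[int, ...]:
    # Row-major, highest plane first: for 9 planes
    # (+4,+3,+2 / +1,0,-1 / -2,-3,-4).
    half = (n_planes - 1) // 2
    return tuple(range(half, -half - 1, -1))


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and photometry of the multiplane imaging system.

    Lengths are micrometres, intensities are camera counts.

    Attributes
    ----------
    plane_spacing
        Axial separation dz between adjacent object planes [um].
    n_planes
        Number of simultaneously imaged planes (odd; plane indices run
        from -(n_planes-1)/2 to +(n_planes-1)/2).
    tile_shape
        (rows, cols) of sub-images in the camera frame.
    tile_layout
        Plane index of each tile in row-major order; must be a bijection
        onto the plane-index range.  The physical arrangement depends on the
        grating orientation, so it is configuration, not a constant.
    pixel_size
        Object-space pixel pitch [um/pixel].
    tile_pixels
        Side length of each (square) sub-image [pixels].
    background_level
        Uniform background [counts].
    bead_diameter
        Bead diameter [um].
    psf_sigma0
        In-focus Gaussian blur width [um].
    defocus_slope
        Growth of the blur width per micrometre of defocus [dimensionless].
    contrast
        In-focus peak signal above background [counts].
    noise_model
        "poisson" or "none".
    """

    plane_spacing: float = 0.88
    n_planes: int = 9
    tile_shape: tuple[int, int] = (3, 3)
    tile_layout: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    pixel_size: float = 0.1833
    tile_pixels: int = 64
    background_level: float = 100.0
    bead_diameter: float = 3.0
    psf_sigma0: float = 0.15
    defocus_slope: float = 0.35
    contrast: float = 400.0
    noise_model: str = "poisson"

    def __post_init__(self) -> None:
        if self.plane_spacing <= 0:
            raise InvalidParameterError("plane_spacing must be positive")
        if self.n_planes < 1 or self.n_planes % 2 == 0:
            raise InvalidParameterError("n_planes must be a positive odd integer")
        rows, cols = self.tile_shape
        if rows * cols != self.n_planes:
            raise InvalidParameterError(
                f"tile_shape {self.tile_shape} holds {rows * cols} tiles "
                f"but n_planes is {self.n_planes}"
            )
        layout = self.tile_layout
        if layout is None:
            layout = _default_layout(self.n_planes)
        layout = tuple(int(n) for n in layout)
        object.__setattr__(self, "tile_layout", layout)
        half = (self.n_planes - 1) // 2
        if sorted(layout) != list(range(-half, half + 1)):
            raise InvalidParameterError(
                f"tile_layout must be a bijection onto {{-{half}..+{half}}}, got {layout}"
            )
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.tile_pixels < 4:
            raise InvalidParameterError("tile_pixels must be >= 4")
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")
        for name in ("bead_diameter", "psf_sigma0", "contrast"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.defocus_slope < 0:
            raise InvalidParameterError("defocus_slope must be >= 0")
        if self.noise_model not in ("none", "poisson"):
            raise InvalidParameterError(
                f"noise_model must be 'none' or 'poisson', got {self.noise_model!r}"
            )

    @property
    def plane_indices(self) -> np.ndarray:
        """Plane indices in ascending order: -(n-1)/2 ... +(n-1)/2."""
        half = (self.n_planes - 1) // 2
        return np.arange(-half, half + 1)

    @property
    def frame_shape(self) -> tuple[int, int]:
        rows, cols = self.tile_shape
        return (rows * self.tile_pixels, cols * self.tile_pixels)

    @property
    def tile_halfwidth_um(self) -> float:
        return 0.5 * self.tile_pixels * self.pixel_size

    def plane_z(self, n: int | np.ndarray) -> np.ndarray | float:
        """Object-space depth of plane ``n`` [um]."""
        return n * self.plane_spacing

    def sigma_at(self, z: float, n: int) -> float:
        """Blur width [um] of the bead at depth ``z`` seen in plane ``n``."""
        defocus = abs(z - self.plane_z(n))
        return float(np.hypot(self.psf_sigma0, self.defocus_slope * defocus))

    def without_noise(self) -> "OpticalConfig":
        return replace(self, noise_model="none")


@dataclass(frozen=True)
class RawFrame:
    """One tiled camera frame: an integer image plus optional ground truth."""

    image: np.ndarray
    timestamp: float = 0.0
    truth: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        image = np.asarray(self.image)
        if image.ndim != 2:
            raise InvalidParameterError("frame image must be 2D")
        if not np.issubdtype(image.dtype, np.integer):
            raise InvalidParameterError("frame image must have an integer dtype")
        if image.min() < 0:
            raise InvalidParameterError("frame image must be non-negative")
        object.__setattr__(self, "image", image)


def _disk_gauss_radial(radii: np.ndarray, disk_radius: float, sigma: float) -> np.ndarray:
    """Uniform disk of given radius convolved with a Gaussian, unit plateau.

    Closed form: the probability that an isotropic 2D normal centred at
    distance ``rho`` with std ``sigma`` lands inside the disk, i.e.
    ``ncx2.cdf((R/sigma)^2, df=2, nc=(rho/sigma)^2)``.
    """
    s2 = sigma * sigma
    return ncx2.cdf(disk_radius**2 / s2, 2, radii**2 / s2)


def _render_tile(
    x: float, y: float, z: float, n: int, config: OpticalConfig
) -> np.ndarray:
    """Expected (noise-free, unquantised) signal of plane ``n``'s sub-image."""
    npx = config.tile_pixels
    centre = (npx - 1) / 2.0
    cols = (np.arange(npx) - centre) * config.pixel_size - x
    rows = (np.arange(npx) - centre) * config.pixel_size - y
    rho = np.hypot(rows[:, None], cols[None, :])

    sigma = config.sigma_at(z, n)
    radius = 0.5 * config.bead_diameter
    # Amplitude fixed by the in-focus peak; the same amplitude at every
    # defocus conserves the integrated signal.
    amplitude = config.contrast / (
        1.0 - np.exp(-(radius**2) / (2.0 * config.psf_sigma0**2))
    )
    # Tabulate the radial profile once and interpolate; exact to < 1e-4
    # of the peak on this grid density.
    rho_max = float(rho.max())
    grid = np.linspace(0.0, rho_max, 1024)
    profile = _disk_gauss_radial(grid, radius, sigma)
    return amplitude * np.interp(rho, grid, profile)


def render_frame(
    position: Sequence[float],
    config: OpticalConfig,
    seed: int | np.random.Generator | None = None,
    timestamp: float = 0.0,
) -> RawFrame:
    """Render one tiled frame of a bead at ``position = (x, y, z)`` [um].

    The lateral position is relative to the centre of each sub-image; the
    bead disk must lie fully inside the tile.  Returns an integer frame with
    the true position recorded in ``truth``.
    """
    x, y, z = (float(v) for v in position)
    radius = 0.5 * config.bead_diameter
    half = config.tile_halfwidth_um
    if abs(x) + radius > half or abs(y) + radius > half:
        raise OutOfBoundsError(
            f"bead at (x={x:g}, y={y:g}) um with radius {radius:g} um exceeds the "
            f"+/-{half:g} um sub-image half-width"
        )
    rows, cols = config.tile_shape
    npx = config.tile_pixels
    expected = np.empty((rows * npx, cols * npx))
    for tile in range(rows * cols):
        r, c = divmod(tile, cols)
        n = config.tile_layout[tile]
        expected[r * npx : (r + 1) * npx, c * npx : (c + 1) * npx] = (
            config.background_level + _render_tile(x, y, z, n, config)
        )
    if config.noise_model == "poisson":
        rng = np.random.default_rng(seed)
        image = rng.poisson(expected).astype(np.uint16)
    else:
        image = np.rint(expected).astype(np.uint16)
    return RawFrame(image=image, timestamp=timestamp, truth=(x, y, z))


def render_trajectory_frames(
    traj: Trajectory,
    config: OpticalConfig,
    seed: int | np.random.Generator | None = None,
) -> list[RawFrame]:
    """Render one frame per trajectory sample, ground truth attached."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(traj.n_frames):
        position = traj.positions[:, i]
        try:
            frames.append(
                render_frame(position, config, seed=rng, timestamp=float(traj.times[i]))
            )
        except OutOfBoundsError as exc:
            raise OutOfBoundsError(f"frame {i}: {exc}") from exc
    return frames


def render_zscan(
    z_positions: Sequence[float],
    config: OpticalConfig,
    seed: int | np.random.Generator | None = None,
) -> list[RawFrame]:
    """Render a calibration scan of a bead fixed at the tile centre.

    Emulates the fixed-bead-in-gel experiment in which a piezo stage steps
    the sample through z; each frame's ``truth`` records the stage position.
    """
    z_positions = np.asarray(z_positions, dtype=float)
    dz = np.diff(z_positions)
    if dz.size and not (np.all(dz > 0) or np.all(dz < 0)):
        raise InvalidParameterError("z_positions must be strictly monotone")
    rng = np.random.default_rng(seed)
    return [
        render_frame((0.0, 0.0, z), config, seed=rng, timestamp=float(i))
        for i, z in enumerate(z_positions)
    ]
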