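"""3D localisation of a bead from tiled multiplane frames.

Pipeline per frame:

1. segment the camera frame into per-plane sub-images;
2. Otsu-threshold the pooled stack and take the intensity-weighted centre of
   mass of the sharpest plane's sub-image for (x, y);
3. subtract a per-plane background (median) and take absolute values, then
   evaluate the sharpness metric

       S = sum(I**2 - I) / (sum I)**2

   for each plane, which peaks in the plane nearest focus;
4. combine the per-plane sharpness values into two axial estimates:

   * the centre of sharpness ``z_cs`` — the sharpness-weighted mean of the
     plane depths: smooth, but biased toward zero because only a handful of
     planes sample the sharpness curve;
   * the sharpest-plane estimate ``z_sp`` — the depth of the sharpest plane
     nudged a quarter spacing toward the second sharpest, quantised on the
     half-spacing lattice ``{n*dz +/- dz/4}``;

5. calibrate in situ by linearly fitting the stepped ``z_sp`` against
   ``z_cs`` over a sweep of the bead through z, and rescale:
   ``z_rcs = gradient * (z_cs - centre) + offset``.  The gradient (about 3-5
   for typical configurations) undoes the undersampling bias and is specific
   to the bead and illumination, which is what makes the calibration
   self-contained — no stage or separate calibration sample is needed during
   a measurement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    CalibrationError,
    DegenerateImageError,
    FormatError,
    InsufficientRangeError,
    InsufficientScanError,
    NoObjectError,
)
from .imaging import OpticalConfig, RawFrame

__all__ = [
    "PlaneStack",
    "SharpnessProfile",
    "CalibrationModel",
    "TrackingResult",
    "split_frame",
    "otsu_threshold",
    "xy_centroid",
    "sharpness",
    "preprocess_for_sharpness",
    "sharpness_profile",
    "center_of_sharpness",
    "sharpest_plane_z",
    "fit_calibration",
    "apply_calibration",
    "track",
    "characterize_plane_spacing",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlaneStack:
    """Per-plane sub-images of one camera frame, in tile (row-major) order."""

    sub_images: np.ndarray  # (n_planes, N, N)
    plane_indices: np.ndarray  # plane index n of each sub-image
    plane_spacing: float

    def __post_init__(self) -> None:
        sub = np.asarray(self.sub_images)
        idx = np.asarray(self.plane_indices, dtype=int)
        if sub.ndim != 3 or sub.shape[0] != idx.size:
            raise FormatError("sub_images must be (n_planes, N, M) matching plane_indices")
        if np.unique(idx).size != idx.size:
            raise FormatError("plane_indices must be distinct")
        object.__setattr__(self, "sub_images", sub)
        object.__setattr__(self, "plane_indices", idx)

    @property
    def plane_z(self) -> np.ndarray:
        """Depth of each sub-image's object plane [um]."""
        return self.plane_indices * self.plane_spacing

    def plane(self, n: int) -> np.ndarray:
        """Sub-image of plane index ``n``."""
        where = np.nonzero(self.plane_indices == n)[0]
        if where.size == 0:
            raise FormatError(f"no sub-image for plane index {n}")
        return self.sub_images[where[0]]


@dataclass(frozen=True)
class SharpnessProfile:
    """Sharpness of each plane's sub-image, aligned with ``plane_indices``."""

    values: np.ndarray
    plane_indices: np.ndarray
    plane_spacing: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        idx = np.asarray(self.plane_indices, dtype=int)
        if values.shape != idx.shape:
            raise FormatError("values and plane_indices must have the same shape")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise FormatError("sharpness values must be finite and non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "plane_indices", idx)

    @property
    def plane_z(self) -> np.ndarray:
        return self.plane_indices * self.plane_spacing


@dataclass(frozen=True)
class CalibrationModel:
    """Linear rescaling of the centre of sharpness onto the sharpest-plane scale.

    ``z_rcs = gradient * (z_cs - center) + offset``; ``center`` is the median
    of the calibration-sweep ``z_cs`` values (so the trap centre maps to ~0)
    and ``offset`` is the fitted intercept (near zero by construction).
    """

    gradient: float
    offset: float
    center: float
    fit_range: tuple[float, float]
    n_points: int
    plane_spacing: float

    def __post_init__(self) -> None:
        if self.gradient <= 0:
            raise CalibrationError(f"calibration gradient must be positive, got {self.gradient!r}")
        if not self.fit_range[0] <= self.fit_range[1]:
            raise CalibrationError("fit_range must be a non-empty interval")


@dataclass(frozen=True)
class TrackingResult:
    """Per-frame localisation output of :func:`track`."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z_cs: np.ndarray
    z_sp: np.ndarray
    z_rcs: np.ndarray
    sharpest_plane: np.ndarray
    sharpness: np.ndarray  # (n_frames, n_planes), ascending plane index
    plane_indices: np.ndarray
    calibration: CalibrationModel
    frame_rate: float | None = None

    @property
    def n_frames(self) -> int:
        return self.times.size


def split_frame(frame: RawFrame, config: OpticalConfig) -> PlaneStack:
    """Segment a tiled frame into its per-plane sub-images (lossless)."""
    rows, cols = config.tile_shape
    image = frame.image
    expected = config.frame_shape
    if image.shape != expected:
        raise FormatError(
            f"frame shape {image.shape} does not match the configured "
            f"{rows}x{cols} grid of {config.tile_pixels}px tiles (expected {expected})"
        )
    npx = config.tile_pixels
    sub = np.stack(
        [
            image[r * npx : (r + 1) * npx, c * npx : (c + 1) * npx]
            for r in range(rows)
            for c in range(cols)
        ]
    )
    return PlaneStack(
        sub_images=sub,
        plane_indices=np.asarray(config.tile_layout, dtype=int),
        plane_spacing=config.plane_spacing,
    )


def otsu_threshold(stack: PlaneStack) -> float:
    """Otsu threshold over the pooled pixel histogram of all planes.

    Pooling (rather than thresholding plane by plane) keeps a strongly
    defocused plane from losing the bead entirely.
    """
    pixels = np.asarray(stack.sub_images)
    if pixels.size == 0:
        raise DegenerateImageError("empty plane stack")
    if pixels.max() == pixels.min():
        raise DegenerateImageError("constant image stack: no threshold separates it")
    return float(threshold_otsu(pixels.ravel()))


def xy_centroid(
    image: np.ndarray, threshold: float, pixel_size: float = 1.0
) -> tuple[float, float]:
    """Thresholded intensity centre of mass of one sub-image.

    Pixels below ``threshold`` are zeroed; the centre of mass of the
    remaining intensities is returned in micrometres relative to the
    sub-image centre (pixel centres at integer indices; x along columns,
    y along rows).
    """
    image = np.asarray(image, dtype=float)
    masked = np.where(image >= threshold, image, 0.0)
    total = masked.sum()
    if total <= 0:
        raise NoObjectError("no pixels at or above the threshold")
    n_rows, n_cols = image.shape
    col_idx = np.arange(n_cols) - (n_cols - 1) / 2.0
    row_idx = np.arange(n_rows) - (n_rows - 1) / 2.0
    x = float((masked.sum(axis=0) @ col_idx) / total) * pixel_size
    y = float((masked.sum(axis=1) @ row_idx) / total) * pixel_size
    return x, y


def sharpness(image: np.ndarray) -> float:
    """Sharpness metric S = sum(I^2 - I) / (sum I)^2.

    Expects a background-subtracted, absolute-valued sub-image (see
    :func:`preprocess_for_sharpness`).  The metric peaks when the bead is in
    focus and falls off as defocus spreads the same integrated signal over
    more pixels.
    """
    image = np.asarray(image, dtype=float)
    total = image.sum()
    if total <= 0:
        raise DegenerateImageError("sharpness undefined for an all-zero image")
    return float((np.square(image).sum() - total) / (total * total))


def preprocess_for_sharpness(stack: PlaneStack) -> PlaneStack:
    """Subtract each plane's background (median) and take absolute values.

    The median is robust as long as the bead covers well under half of the
    tile; the absolute value makes the metric indifferent to whether the bead
    appears bright or dark against the background.
    """
    sub = np.asarray(stack.sub_images, dtype=float)
    medians = np.median(sub, axis=(1, 2), keepdims=True)
    return PlaneStack(
        sub_images=np.abs(sub - medians),
        plane_indices=stack.plane_indices,
        plane_spacing=stack.plane_spacing,
    )


def sharpness_profile(stack: PlaneStack) -> SharpnessProfile:
    """Per-plane sharpness of a preprocessed stack."""
    values = np.array([sharpness(img) for img in stack.sub_images])
    return SharpnessProfile(
        values=values,
        plane_indices=stack.plane_indices,
        plane_spacing=stack.plane_spacing,
    )


def center_of_sharpness(profile: SharpnessProfile) -> float:
    """Sharpness-weighted mean of the plane depths [um]."""
    if profile.values.size < 2:
        raise DegenerateImageError("centre of sharpness needs at least 2 planes")
    total = profile.values.sum()
    if total <= 0:
        raise DegenerateImageError("zero total sharpness: degenerate profile")
    return float((profile.plane_z * profile.values).sum() / total)


def _ranked_planes(profile: SharpnessProfile) -> np.ndarray:
    # Sort by sharpness descending; exact ties break toward the plane closer
    # to the mid-plane (then the lower index) so the result is deterministic.
    order = sorted(
        range(profile.values.size),
        key=lambda i: (
            -profile.values[i],
            abs(int(profile.plane_indices[i])),
            int(profile.plane_indices[i]),
        ),
    )
    return profile.plane_indices[order]


def sharpest_plane_z(profile: SharpnessProfile) -> float:
    """Quantised axial estimate from the two sharpest planes [um].

    ``z_sp = z_sharpest - (z_sharpest - z_2nd_sharpest) / 4``: the sharpest
    plane's depth shifted a quarter spacing toward the runner-up, which for
    adjacent planes yields the half-spacing staircase ``{n*dz +/- dz/4}``.
    """
    if profile.values.size < 2:
        raise DegenerateImageError("sharpest-plane estimate needs at least 2 planes")
    ranked = _ranked_planes(profile)
    z1 = ranked[0] * profile.plane_spacing
    z2 = ranked[1] * profile.plane_spacing
    return float(z1 - (z1 - z2) / 4.0)


def fit_calibration(
    z_cs_series: np.ndarray,
    z_sp_series: np.ndarray,
    config: OpticalConfig,
    sharpest_plane: np.ndarray | None = None,
    max_abs_z_sp: float | None = None,
    max_edge_plane: int | None = None,
) -> CalibrationModel:
    """Fit the in-situ linear rescaling of z_cs from a calibration sweep.

    Ordinary least squares of the stepped ``z_sp`` values on median-centred
    ``z_cs``.  To stay in the linear regime, samples are restricted to
    ``|z_sp| <= 2 * dz`` by default and, when ``sharpest_plane`` is given,
    frames whose sharpest plane lies at the edge of the stack (|n| >= 3 by
    default for 9 planes) are dropped.
    """
    z_cs = np.asarray(z_cs_series, dtype=float)
    z_sp = np.asarray(z_sp_series, dtype=float)
    if z_cs.shape != z_sp.shape or z_cs.ndim != 1:
        raise FormatError("z_cs and z_sp series must be equal-length 1D arrays")
    dz = config.plane_spacing
    if max_abs_z_sp is None:
        max_abs_z_sp = 2.0 * dz
    if max_edge_plane is None:
        max_edge_plane = (config.n_planes - 1) // 2 - 1
    keep = np.abs(z_sp) <= max_abs_z_sp + 1e-12
    if sharpest_plane is not None:
        keep &= np.abs(np.asarray(sharpest_plane, dtype=int)) < max_edge_plane
    z_cs, z_sp = z_cs[keep], z_sp[keep]
    n_steps = np.unique(np.round(z_sp / (dz / 2.0)).astype(int)).size
    if z_cs.size < 20 or n_steps < 3:
        raise InsufficientRangeError(
            f"calibration needs >= 20 samples spanning >= 3 distinct z_sp steps; "
            f"got {z_cs.size} samples over {n_steps} steps"
        )
    center = float(np.median(z_cs))
    gradient, offset = np.polyfit(z_cs - center, z_sp, 1)
    if gradient <= 0:
        raise CalibrationError(
            f"calibration fit returned non-positive gradient {gradient:g}"
        )
    return CalibrationModel(
        gradient=float(gradient),
        offset=float(offset),
        center=center,
        fit_range=(float(z_sp.min()), float(z_sp.max())),
        n_points=int(z_cs.size),
        plane_spacing=dz,
    )


def apply_calibration(z_cs: float | np.ndarray, model: CalibrationModel):
    """Rescaled centre of sharpness: gradient * (z_cs - center) + offset."""
    return model.gradient * (np.asarray(z_cs, dtype=float) - model.center) + model.offset


def _locate_frame(frame: RawFrame, config: OpticalConfig):
    stack = split_frame(frame, config)
    threshold = otsu_threshold(stack)
    pre = preprocess_for_sharpness(stack)
    profile = sharpness_profile(pre)
    ranked = _ranked_planes(profile)
    n_sharpest = int(ranked[0])
    x, y = xy_centroid(stack.plane(n_sharpest), threshold, config.pixel_size)
    z_cs = center_of_sharpness(profile)
    z_sp = sharpest_plane_z(profile)
    order = np.argsort(profile.plane_indices)
    return x, y, z_cs, z_sp, n_sharpest, profile.values[order]


def track(
    frames: Sequence[RawFrame],
    config: OpticalConfig,
    calibration: CalibrationModel | str = "self",
    calibration_frames: int | None = None,
) -> TrackingResult:
    """Full localisation pipeline over a frame sequence.

    Parameters
    ----------
    frames
        Tiled camera frames.  For self-calibration the sequence must begin
        with a sweep of the bead through z (the instrument achieves this by
        translating the trapping-beam waist before the measurement proper).
    calibration
        ``"self"`` to fit the rescaling from the first ``calibration_frames``
        frames (all frames if None), or a pre-fitted :class:`CalibrationModel`.
    """
    if len(frames) == 0:
        raise FormatError("track requires at least one frame")
    records = []
    for i, frame in enumerate(frames):
        try:
            records.append(_locate_frame(frame, config))
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    x, y, z_cs, z_sp, n_sharpest, profiles = (
        np.array([r[0] for r in records]),
        np.array([r[1] for r in records]),
        np.array([r[2] for r in records]),
        np.array([r[3] for r in records]),
        np.array([r[4] for r in records], dtype=int),
        np.stack([r[5] for r in records]),
    )
    if isinstance(calibration, CalibrationModel):
        model = calibration
    elif calibration == "self":
        n_cal = len(frames) if calibration_frames is None else int(calibration_frames)
        try:
            model = fit_calibration(
                z_cs[:n_cal], z_sp[:n_cal], config, sharpest_plane=n_sharpest[:n_cal]
            )
        except (InsufficientRangeError, CalibrationError) as exc:
            raise type(exc)(
                f"self-calibration failed over the first {n_cal} frames: {exc}"
            ) from exc
        logger.info(
            "self-calibration: gradient %.3f over %d frames (z_sp range %.2f..%.2f um)",
            model.gradient,
            model.n_points,
            *model.fit_range,
        )
    else:
        raise FormatError(f"calibration must be 'self' or a CalibrationModel, got {calibration!r}")
    z_rcs = apply_calibration(z_cs, model)
    times = np.array([f.timestamp for f in frames], dtype=float)
    dt = np.diff(times)
    frame_rate = None
    if dt.size and np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-6):
        frame_rate = float(1.0 / dt[0])
    return TrackingResult(
        times=times,
        x=x,
        y=y,
        z_cs=z_cs,
        z_sp=z_sp,
        z_rcs=np.asarray(z_rcs),
        sharpest_plane=n_sharpest,
        sharpness=profiles,
        plane_indices=np.sort(np.asarray(config.tile_layout, dtype=int)),
        calibration=model,
        frame_rate=frame_rate,
    )


def characterize_plane_spacing(
    zscan_frames: Sequence[RawFrame],
    stage_z: Sequence[float],
    config: OpticalConfig,
    peak_halfwidth_um: float = 0.4,
) -> float:
    """Estimate the inter-plane spacing from a fixed-bead stage scan [um].

    For each plane, the stage position that maximises that plane's sharpness
    is located by parabolic interpolation: a quadratic is fitted to the
    sharpness samples within ``peak_halfwidth_um`` of the discrete argmax
    (at least the 3 nearest points), since the stage steps under-sample the
    peak and single-sample shot noise would dominate a 3-point vertex.  The
    spacing is the slope of the best-fit line of peak position against plane
    index.  This reproduces the one-off characterisation done when the
    instrument is installed.
    """
    stage_z = np.asarray(stage_z, dtype=float)
    if stage_z.ndim != 1 or stage_z.size != len(zscan_frames):
        raise FormatError("stage_z must be 1D with one entry per frame")
    if stage_z.size < 3:
        raise InsufficientScanError("scan needs at least 3 stage positions")
    if not (np.all(np.diff(stage_z) > 0) or np.all(np.diff(stage_z) < 0)):
        raise FormatError("stage_z must be strictly monotone")

    profiles = []
    for frame in zscan_frames:
        pre = preprocess_for_sharpness(split_frame(frame, config))
        prof = sharpness_profile(pre)
        order = np.argsort(prof.plane_indices)
        profiles.append(prof.values[order])
    sharp = np.stack(profiles)  # (n_frames, n_planes)
    plane_indices = np.sort(np.asarray(config.tile_layout, dtype=int))

    step = float(np.median(np.abs(np.diff(stage_z))))
    halfwidth = max(1, int(round(peak_halfwidth_um / step)))
    peaks, used = [], []
    for j, n in enumerate(plane_indices):
        i = int(np.argmax(sharp[:, j]))
        if i == 0 or i == stage_z.size - 1:
            warnings.warn(
                f"plane {n}: sharpness maximum at the scan boundary; plane excluded",
                stacklevel=2,
            )
            continue
        lo, hi = max(0, i - halfwidth), min(stage_z.size, i + halfwidth + 1)
        zwin = stage_z[lo:hi]
        a, b, _ = np.polyfit(zwin, sharp[lo:hi, j], 2)
        vertex = -b / (2.0 * a)
        if a >= 0 or not (zwin.min() <= vertex <= zwin.max()):
            warnings.warn(f"plane {n}: no interior sharpness maximum; plane excluded", stacklevel=2)
            continue
        peaks.append(vertex)
        used.append(n)
    if len(used) < 3:
        raise InsufficientScanError(
            f"only {len(used)} planes had an interior sharpness maximum; need >= 3"
        )
    slope, _ = np.polyfit(used, peaks, 1)
    return float(slope)
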