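"""Polar unwrapping and cambial-landmark alignment of cross-sections.

The projection pipeline turns an annotated cross-section into a
comparable, landmark-anchored profile in three steps:

1. :func:`rotate_section` -- rotate the image about the root centre so the
   primary-xylem axis is vertical, giving all samples a common angular
   frame;
2. :func:`unwrap` -- sample intensities along rays from the centre to the
   image edge, producing an angle x radius grid (bilinear interpolation;
   rays are truncated, never extrapolated, at the image border);
3. :func:`align_to_landmark` -- shift every angular column by an integer
   number of radial bins so the annotated cambial landmark (the most
   recent division wall) sits on one common reference row.

:func:`aggregate` then averages many aligned maps per treatment into a
:class:`ProjectionStack` of per-cell mean, sd and n, so fluorescence
distributions can be compared across samples at matched distance from the
cambium rather than from the (growth-dependent) root centre.

Conventions: image x rightward, y downward, 0-based; angles in degrees
counter-clockwise from the vertical (up) axis; radius bin 0 at the centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import rotate as _sk_rotate

from .synthetic_cambium import RadialSection

__all__ = [
    "PolarMap",
    "AlignedPolarMap",
    "ProjectionStack",
    "rotate_section",
    "unwrap",
    "interpolate_polyline",
    "align_to_landmark",
    "aggregate",
]


@dataclass
class PolarMap:
    """Angle x radius intensity grid, one plane per channel.

    ``grid`` has shape (n_channels, n_angle_bins, n_radius_bins); bin
    (i, j) holds the interpolated intensity at angle ``i * 360 /
    n_angle_bins`` (CCW from vertical) and radius ``j * radial_step``
    pixels from the centre.  ``valid`` masks bins whose sample point fell
    inside the image.
    """

    grid: np.ndarray
    valid: np.ndarray
    channels: list
    radial_step: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_angle_bins(self) -> int:
        return self.grid.shape[1]

    @property
    def n_radius_bins(self) -> int:
        return self.grid.shape[2]

    def masked_fraction(self) -> float:
        return float(1.0 - self.valid.mean())


@dataclass
class AlignedPolarMap(PolarMap):
    """A PolarMap whose columns are shifted to a common landmark row."""

    reference_row: int = 0
    shifts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    landmark_bins: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class ProjectionStack:
    """Per-bin mean/sd/n across a set of aligned maps of one treatment."""

    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    channels: list
    radial_step: float
    reference_row: int
    treatment: str = ""


def rotate_section(section: RadialSection, order: int = 1) -> RadialSection:
    """Rotate a section about its centre so the xylem axis is vertical.

    Interpolation is bilinear (``order=1``) by default; pixels rotated in
    from outside the frame are zero.  The landmark polyline angles and the
    axis annotation are transformed consistently; the centre is the
    rotation pivot and is unchanged.
    """
    if section.xylem_axis_angle is None:
        raise ValueError("xylem_axis_angle annotation is required")
    delta = 90.0 - section.xylem_axis_angle
    if abs(delta % 360.0) < 1e-12:
        image = section.image.copy()
    else:
        image = np.stack(
            [
                _sk_rotate(
                    ch,
                    delta,
                    center=section.centre,
                    order=order,
                    preserve_range=True,
                    resize=False,
                )
                for ch in section.image
            ]
        )
    poly = section.landmark_polyline.copy()
    poly[:, 0] = (poly[:, 0] + delta) % 360.0
    return RadialSection(
        image=image,
        channels=list(section.channels),
        centre=section.centre,
        xylem_axis_angle=90.0,
        landmark_polyline=poly,
        pixel_size=section.pixel_size,
        files=list(section.files),
    )


def unwrap(
    section: RadialSection,
    n_angle_bins: int = 360,
    radial_step: float = 1.0,
    max_radius: Optional[float] = None,
    order: int = 1,
) -> PolarMap:
    """Sample a section from the centre outward into a polar grid.

    Rays leave the centre at ``n_angle_bins`` evenly spaced angles and are
    sampled every ``radial_step`` pixels out to ``max_radius`` (default:
    the distance from the centre to the farthest image corner).  Samples
    beyond the image border are masked, not extrapolated.
    """
    if n_angle_bins < 8:
        raise ValueError("need n_angle_bins >= 8")
    if radial_step <= 0:
        raise ValueError("radial_step must be positive")
    h, w = section.image.shape[1:]
    cx, cy = section.centre
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("centre lies outside the image")
    if max_radius is None:
        corners = [(0, 0), (0, h - 1), (w - 1, 0), (w - 1, h - 1)]
        max_radius = max(np.hypot(cx - x, cy - y) for x, y in corners)
    n_rad = int(np.ceil(max_radius / radial_step))

    ang = np.radians(np.arange(n_angle_bins) * (360.0 / n_angle_bins))
    rad = np.arange(n_rad) * radial_step
    # direction of angle theta (CCW from up, y down): (dx, dy) = (-sin, -cos)
    dx = -np.sin(ang)[:, None] * rad[None, :]
    dy = -np.cos(ang)[:, None] * rad[None, :]
    cols = cx + dx
    rows = cy + dy
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)

    grid = np.empty((section.image.shape[0], n_angle_bins, n_rad))
    for k, ch in enumerate(section.image):
        grid[k] = map_coordinates(
            ch, [rows, cols], order=order, mode="constant", cval=0.0
        )
    grid[:, ~valid] = np.nan

    return PolarMap(
        grid=grid,
        valid=valid,
        channels=list(section.channels),
        radial_step=radial_step,
        metadata={
            "centre": tuple(section.centre),
            "pixel_size": section.pixel_size,
            "angle_convention": "deg CCW from vertical (up) axis",
            "n_angle_bins": n_angle_bins,
        },
    )


def interpolate_polyline(
    polyline: np.ndarray, n_angle_bins: int
) -> np.ndarray:
    """Resample a (angle_deg, radius) polyline onto the angular bin grid.

    Linear interpolation in (angle, radius), periodic over 360 deg, so
    annotation gaps between sampled angles are filled.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) == 0:
        raise ValueError("polyline must be a non-empty (n, 2) array")
    order = np.argsort(poly[:, 0] % 360.0)
    ang = poly[order, 0] % 360.0
    rad = poly[order, 1]
    bin_angles = np.arange(n_angle_bins) * (360.0 / n_angle_bins)
    return np.interp(bin_angles, ang, rad, period=360.0)


def align_to_landmark(
    pmap: PolarMap,
    landmark_polyline: np.ndarray,
    reference_row: Optional[int] = None,
) -> AlignedPolarMap:
    """Shift each angular column so the landmark sits at one common row.

    Shifts are whole radial bins (raw intensities are preserved; landmark
    annotation precision is about one cell anyway).  Bins shifted in from
    beyond the grid are masked.  Columns whose landmark radius is
    non-positive or beyond the ray length are masked entirely, with a
    warning.  The default ``reference_row`` is the largest landmark bin,
    so no column loses inner bins to the shift.
    """
    radii = interpolate_polyline(landmark_polyline, pmap.n_angle_bins)
    bins = np.rint(radii / pmap.radial_step).astype(int)
    bad = (radii <= 0) | (bins >= pmap.n_radius_bins)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} angular columns have landmark radii outside "
            "the sampled range; masking them",
            stacklevel=2,
        )
    if reference_row is None:
        good_bins = bins[~bad]
        if good_bins.size == 0:
            raise ValueError("no usable landmark radii")
        reference_row = int(good_bins.max())
    shifts = reference_row - bins

    n_ch, n_ang, n_rad = pmap.grid.shape
    grid = np.full_like(pmap.grid, np.nan)
    valid = np.zeros_like(pmap.valid)
    for j in range(n_ang):
        if bad[j]:
            continue
        s = shifts[j]
        src_lo, src_hi = max(0, -s), min(n_rad, n_rad - s)
        dst_lo, dst_hi = max(0, s), min(n_rad, n_rad + s)
        grid[:, j, dst_lo:dst_hi] = pmap.grid[:, j, src_lo:src_hi]
        valid[j, dst_lo:dst_hi] = pmap.valid[j, src_lo:src_hi]
    grid[:, ~valid] = np.nan

    meta = dict(pmap.metadata)
    meta["reference_row"] = int(reference_row)
    return AlignedPolarMap(
        grid=grid,
        valid=valid,
        channels=list(pmap.channels),
        radial_step=pmap.radial_step,
        metadata=meta,
        reference_row=int(reference_row),
        shifts=shifts,
        landmark_bins=np.where(bad, -1, bins),
    )


def _check_geometry(maps: Sequence[AlignedPolarMap]) -> None:
    first = maps[0]
    for m in maps[1:]:
        if (
            m.grid.shape != first.grid.shape
            or m.radial_step != first.radial_step
            or m.reference_row != first.reference_row
            or m.channels != first.channels
        ):
            raise ValueError("maps have mixed bin geometries or reference rows")


def aggregate(maps: Iterable[AlignedPolarMap], treatment: str = "") -> ProjectionStack:
    """Per-bin mean, sd and n over aligned maps (order-independent).

    Values are sorted per bin before summation so the result is
    bit-identical under any permutation of the input list.  sd is the
    population standard deviation over contributing maps (0 where n == 1);
    bins with n == 0 are NaN-masked.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to aggregate")
    _check_geometry(maps)
    stack = np.stack([m.grid for m in maps])  # (k, ch, ang, rad)
    stack = np.sort(stack, axis=0)  # NaNs sort last -> order invariance
    n = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=0)
    mean[n == 0] = np.nan
    sd[n == 0] = np.nan
    return ProjectionStack(
        mean=mean,
        sd=sd,
        n=n,
        channels=list(maps[0].channels),
        radial_step=maps[0].radial_step,
        reference_row=maps[0].reference_row,
        treatment=treatment,
    )
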