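"""Plane-induced binocular projection geometry.

The viewing geometry follows standard camera geometry with zero vergence:
both eyes' nodal points lie on the x-axis at ``x = -a`` (left eye) and
``x = +a`` (right eye), with the cyclopean axis along z.  Both eyes project
onto a single shared (cyclopean) image plane at ``z = D``.  Image
coordinates are expressed in degrees through the tangent mapping
``X_screen = D * tan(x_deg)``; the same raster is used for both eyes, so a
surface coincident with the image plane produces zero disparity.

A planar surface is parametrized by its slant ``s`` (rotation away from
frontoparallel), tilt ``tau`` (direction of the depth gradient in the image
plane; tilt 0 means the depth gradient is horizontal), and intercept
distance ``zeta`` (where the plane crosses the cyclopean axis):

    Z = zeta + tan(s) * (X * cos(tau) + Y * sin(tau))

With tilt 0 a positive slant puts the right half of the surface
(``X > 0``) farther from the observer.

Sign conventions (tilt 0):

    slant > 0   right side farther, left side nearer
    zeta > D    surface behind the image plane, uncrossed disparity
    zeta < D    surface in front of the image plane, crossed disparity
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Tuple

import numpy as np
from scipy import ndimage


DEG = np.pi / 180.0


class Direction(Enum):
    """Prediction direction: which eye is the source of gray levels."""

    R2L = "R2L"  # predict the left image from the right image
    L2R = "L2R"

    @property
    def source(self) -> str:
        return "R" if self is Direction.R2L else "L"

    @property
    def destination(self) -> str:
        return "L" if self is Direction.R2L else "R"

    def reversed(self) -> "Direction":
        return Direction.L2R if self is Direction.R2L else Direction.R2L


class DegenerateGeometryError(ValueError):
    """Raised when a ray misses the surface or hits it behind the eyes."""


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer and raster parameters.

    Parameters
    ----------
    interocular_distance : float
        Distance ``2a`` between the nodal points, cm.
    image_plane_distance : float
        Distance ``D`` of the shared cyclopean image plane, cm.
    pixels_per_degree : float
        Raster sampling density.
    image_extent : tuple of float
        (width, height) of the default raster in degrees.
    """

    interocular_distance: float = 6.5
    image_plane_distance: float = 100.0
    pixels_per_degree: float = 48.0
    image_extent: Tuple[float, float] = (2.23, 2.12)

    def __post_init__(self) -> None:
        if self.interocular_distance < 0:
            raise ValueError("interocular_distance must be >= 0")
        if self.image_plane_distance <= 0:
            raise ValueError("image_plane_distance must be > 0")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be > 0")

    @property
    def a(self) -> float:
        """Half the interocular distance, cm."""
        return 0.5 * self.interocular_distance

    def eye_x(self, eye: str) -> float:
        """x-offset of an eye's nodal point, cm ('L' or 'R')."""
        if eye == "L":
            return -self.a
        if eye == "R":
            return self.a
        raise ValueError(f"eye must be 'L' or 'R', got {eye!r}")

    @property
    def nyquist(self) -> float:
        """Nyquist frequency of the raster, cycles/degree."""
        return 0.5 * self.pixels_per_degree


@dataclass(frozen=True)
class PlaneParams:
    """Global plane parametrization (slant, tilt, intercept distance)."""

    slant: float  # degrees, |slant| < 90
    tilt: float = 0.0  # degrees in [0, 360)
    intercept_distance: float = 100.0  # zeta, cm

    def __post_init__(self) -> None:
        if not abs(self.slant) < 90:
            raise ValueError("|slant| must be < 90 degrees")
        if self.intercept_distance <= 0:
            raise ValueError("intercept_distance must be > 0")


@dataclass(frozen=True)
class LocalPlaneParams:
    """Local patch parametrization: slant and distance of the patch-center
    surface point, as seen from a given eye.

    ``distance`` is the z-coordinate of the surface point along the eye's
    ray through the patch center.  The equivalent intercept distance is
    ``zeta_i = z_i - x_i * tan(s_i)`` where ``x_i`` is the lateral (X)
    position of that surface point in cm.
    """

    slant: float  # s_i, degrees
    distance: float  # z_i, cm
    patch_center: Tuple[float, float] = (0.0, 0.0)  # (x, y), degrees

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be > 0")


@dataclass(frozen=True)
class Window:
    """Axis-aligned angular rectangle with an implied pixel raster.

    Pixel centers are placed symmetrically about the window center at a
    spacing of ``1 / pixels_per_degree``.
    """

    center: Tuple[float, float] = (0.0, 0.0)  # degrees
    width: float = 2.23  # degrees
    height: float = 2.12  # degrees

    def shape(self, vg: ViewingGeometry) -> Tuple[int, int]:
        ny = max(1, int(round(self.height * vg.pixels_per_degree)))
        nx = max(1, int(round(self.width * vg.pixels_per_degree)))
        return ny, nx

    def axes(self, vg: ViewingGeometry) -> Tuple[np.ndarray, np.ndarray]:
        """1-D pixel-center coordinates (y_deg, x_deg)."""
        ny, nx = self.shape(vg)
        step = 1.0 / vg.pixels_per_degree
        x = self.center[0] + (np.arange(nx) - (nx - 1) / 2.0) * step
        y = self.center[1] + (np.arange(ny) - (ny - 1) / 2.0) * step
        return y, x

    def grid(self, vg: ViewingGeometry) -> Tuple[np.ndarray, np.ndarray]:
        """2-D meshgrid of pixel-center coordinates (y_deg, x_deg)."""
        y, x = self.axes(vg)
        return np.meshgrid(y, x, indexing="ij")

    def expanded(self, margin_x: float, margin_y: float) -> "Window":
        return replace(
            self, width=self.width + 2 * margin_x, height=self.height + 2 * margin_y
        )

    def contains(self, x: float, y: float) -> bool:
        return (
            abs(x - self.center[0]) <= self.width / 2
            and abs(y - self.center[1]) <= self.height / 2
        )


def _plane_trig(plane: PlaneParams) -> Tuple[float, float, float]:
    ts = np.tan(plane.slant * DEG)
    ct = np.cos(plane.tilt * DEG)
    st = np.sin(plane.tilt * DEG)
    return ts, ct, st


def surface_point(
    x_deg: np.ndarray,
    y_deg: np.ndarray,
    plane: PlaneParams,
    vg: ViewingGeometry,
    eye: str,
):
    """Intersect eye rays through image points with the plane.

    Returns ``(X, Y, Z, valid)`` where (X, Y, Z) are cyclopean coordinates
    in cm of the surface point seen at each image position, and ``valid``
    marks rays that hit the plane in front of the eyes.
    """
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.asarray(y_deg, dtype=float)
    D = vg.image_plane_distance
    e = vg.eye_x(eye)
    ts, ct, st = _plane_trig(plane)

    tx = np.tan(x_deg * DEG)
    ty = np.tan(y_deg * DEG)
    # ray: P(t) = (e, 0, 0) + t * (D*tx - e, D*ty, D)
    denom = D - ts * ((D * tx - e) * ct + D * ty * st)
    num = plane.intercept_distance + ts * e * ct
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    valid = np.isfinite(t) & (t > 0)
    X = e + t * (D * tx - e)
    Y = t * D * ty
    Z = t * D
    return X, Y, Z, valid


def project_to_eye(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    vg: ViewingGeometry,
    eye: str,
):
    """Project 3D points through an eye's nodal point onto the shared
    image plane; returns angular image coordinates in degrees."""
    D = vg.image_plane_distance
    e = vg.eye_x(eye)
    with np.errstate(divide="ignore", invalid="ignore"):
        Xs = e + (X - e) * (D / Z)
        Ys = Y * (D / Z)
    x_deg = np.arctan2(Xs, D) / DEG
    y_deg = np.arctan2(Ys, D) / DEG
    return x_deg, y_deg


def map_between_eyes(
    x_deg,
    y_deg,
    plane: PlaneParams,
    vg: ViewingGeometry,
    direction: Direction,
    strict: bool = False,
):
    """Map image points in the source eye to the destination eye through
    the plane.

    The map is the composition of back projection (source eye ray to the
    plane) and forward projection (plane point to the destination eye's
    image).  It is exactly inverted by swapping the direction.

    Returns ``(x', y', valid)`` in degrees.  With ``strict=True`` a
    degenerate geometry (ray parallel to the plane, or intersection behind
    the nodal points) raises :class:`DegenerateGeometryError` instead of
    being flagged.
    """
    X, Y, Z, valid = surface_point(x_deg, y_deg, plane, vg, direction.source)
    if strict and not np.all(valid):
        raise DegenerateGeometryError(
            "ray misses the plane or intersects behind the eyes"
        )
    xo, yo = project_to_eye(X, Y, Z, vg, direction.destination)
    return xo, yo, valid


def image_to_pixel(
    x_deg: np.ndarray, y_deg: np.ndarray, window: Window, vg: ViewingGeometry
):
    """Convert angular coordinates to fractional pixel indices (row, col)
    on a window's raster."""
    yax, xax = window.axes(vg)
    col = (x_deg - xax[0]) * vg.pixels_per_degree
    row = (y_deg - yax[0]) * vg.pixels_per_degree
    return row, col


def spline_coeffs(img: np.ndarray, order: int = 5) -> np.ndarray:
    """Precompute interpolation coefficients for repeated resampling."""
    return ndimage.spline_filter(img, order=order, mode="constant", output=np.float64)


def sample_image(
    coeffs: np.ndarray,
    row: np.ndarray,
    col: np.ndarray,
    order: int = 5,
) -> np.ndarray:
    """Sample a spline-filtered image at fractional pixel positions."""
    return ndimage.map_coordinates(
        coeffs,
        np.stack([row, col]),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def predict_image(
    src: np.ndarray,
    plane: PlaneParams,
    vg: ViewingGeometry,
    direction: Direction,
    src_window: Window | None = None,
    dst_window: Window | None = None,
    order: int = 5,
    src_coeffs: np.ndarray | None = None,
    edge_margin: int | None = None,
):
    """Predict the destination-eye image from the source-eye image through
    a candidate plane.

    Every destination-raster pixel is mapped back through the plane to the
    source raster and the source image is resampled there with a separable
    spline interpolant (exact at grid nodes).  Pixels whose pre-image falls
    outside the source raster — or within ``edge_margin`` pixels of its
    border, where the interpolant's support crosses the edge (default: the
    spline half-support) — are flagged invalid.

    Returns ``(pred, valid)``; invalid pixels are set to 0 in ``pred``.
    """
    src_window = src_window or Window(width=vg.image_extent[0], height=vg.image_extent[1])
    dst_window = dst_window or src_window
    if edge_margin is None:
        edge_margin = (order + 1) // 2
    yg, xg = dst_window.grid(vg)
    # destination pixel -> corresponding source-image location
    xs, ys, valid = map_between_eyes(xg, yg, plane, vg, direction.reversed())
    row, col = image_to_pixel(xs, ys, src_window, vg)
    ny, nx = src.shape
    m = edge_margin
    inside = (row >= m) & (row <= ny - 1 - m) & (col >= m) & (col <= nx - 1 - m)
    valid = valid & inside
    if not np.any(valid):
        raise DegenerateGeometryError("no destination pixel has a valid pre-image")
    coeffs = src_coeffs if src_coeffs is not None else spline_coeffs(src, order)
    pred = sample_image(coeffs, row, col, order=order)
    pred[~valid] = 0.0
    return pred, valid


def transfer_receptive_field(
    rf: np.ndarray,
    plane: PlaneParams,
    vg: ViewingGeometry,
    window: Window | None = None,
    direction: Direction = Direction.R2L,
    order: int = 5,
):
    """Transfer a receptive-field weighting from one eye to the other
    through a plane.

    The transferred field assigns to each destination-eye image point the
    source-eye weight of the same 3D surface point; a binocular neuron
    matched to the plane would pair these two monocular fields.  Also
    returns the energy (sum of squared differences) between the original
    and transferred fields on the common raster.
    """
    window = window or Window(width=vg.image_extent[0], height=vg.image_extent[1])
    rf_other, valid = predict_image(
        rf, plane, vg, direction, src_window=window, dst_window=window, order=order
    )
    diff_energy = float(np.sum((rf - rf_other)[valid] ** 2))
    return rf_other, diff_energy


def local_to_global(
    local: LocalPlaneParams, vg: ViewingGeometry, eye: str = "R"
) -> PlaneParams:
    """Convert a (slant, patch distance) pair to global plane parameters.

    The patch-center surface point sits on the eye's ray through the patch
    center at depth ``z_i``; its lateral position ``x_i`` (cm) gives the
    intercept distance via ``zeta_i = z_i - x_i * tan(s_i)`` (tilt 0).
    """
    D = vg.image_plane_distance
    e = vg.eye_x(eye)
    tx = np.tan(local.patch_center[0] * DEG)
    # lateral position of the surface point at depth z on the eye ray
    x_lat = e + (D * tx - e) * (local.distance / D)
    zeta = local.distance - x_lat * np.tan(local.slant * DEG)
    if zeta <= 0:
        raise DegenerateGeometryError("local plane has non-positive intercept")
    return PlaneParams(slant=local.slant, tilt=0.0, intercept_distance=zeta)


def global_to_local(
    plane: PlaneParams,
    patch_center: Tuple[float, float],
    vg: ViewingGeometry,
    eye: str = "R",
) -> LocalPlaneParams:
    """Distance of the patch-center surface point for a global plane."""
    if plane.tilt % 360 != 0:
        raise ValueError("local parametrization assumes tilt 0")
    X, Y, Z, valid = surface_point(
        patch_center[0], patch_center[1], plane, vg, eye
    )
    if not valid:
        raise DegenerateGeometryError("patch-center ray misses the plane")
    return LocalPlaneParams(
        slant=plane.slant, distance=float(Z), patch_center=patch_center
    )
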