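"""Ellipse fitting, concentric-ellipse constructions, polar unwrapping, and
vertex-angle metrology.

The elliptical "radius" of a point is defined as the factor ``f`` such that
the point lies on the fitted ellipse scaled by ``f`` about its own center;
for a circle this reduces to the ordinary normalized radius. This makes the
donut/disk split and the unwrap axis exact for ellipses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import EllipseModel as _SkimageEllipseModel

from .image import ImageFrame

__all__ = [
    "EllipseModel",
    "VertexAnnotation",
    "fit_ellipse",
    "scale_ellipse",
    "classify_points",
    "elliptical_radius",
    "vertex_angle",
    "trifurrow_angles",
    "estimate_ray_bearings",
    "polar_unwrap",
    "ellipse_band_profile",
    "ellipse_perimeter",
    "plateau_tetrahedral_angle",
    "regular_polygon_interior_angle",
    "EQUAL_AREA_FACTOR",
]

#: Scale factor at which the inner ellipse encloses exactly half the area.
EQUAL_AREA_FACTOR = math.sqrt(0.5)


@dataclass(frozen=True)
class EllipseModel:
    """Fitted boundary ellipse: center (px), semi-axes (px), orientation (rad).

    Invariants: ``a >= b > 0`` and ``theta`` in ``[0, pi)``. ``residual_rms``
    is the RMS orthogonal-ish residual of the fit when produced by
    :func:`fit_ellipse`, else ``None``.
    """

    center_x: float
    center_y: float
    a: float
    b: float
    theta: float
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        a, b, theta = self.a, self.b, self.theta
        if not (b > 0 and a > 0):
            raise ValueError("semi-axes must be positive")
        if a < b:  # normalize so a is the semi-major axis
            a, b = b, a
            theta = theta + math.pi / 2
        theta = theta % math.pi
        object.__setattr__(self, "a", float(a))
        object.__setattr__(self, "b", float(b))
        object.__setattr__(self, "theta", float(theta))

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def point_at(self, t: float | np.ndarray, f: float = 1.0) -> np.ndarray:
        """Point(s) on the ellipse scaled by ``f`` at parametric angle ``t``.

        Returns an array of shape ``(..., 2)`` with (x, y) columns.
        """
        t = np.asarray(t, dtype=float)
        ct, st = np.cos(self.theta), np.sin(self.theta)
        ex = f * self.a * np.cos(t)
        ey = f * self.b * np.sin(t)
        x = self.center_x + ex * ct - ey * st
        y = self.center_y + ex * st + ey * ct
        return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class VertexAnnotation:
    """A node where three furrows meet: the vertex plus three ray endpoints."""

    vertex: tuple[float, float]
    rays: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.rays) != 3:
            raise ValueError("a tri-furrow annotation needs exactly three rays")
        v = np.asarray(self.vertex, dtype=float)
        for p in self.rays:
            if np.allclose(np.asarray(p, dtype=float), v):
                raise ValueError("ray endpoint coincides with the vertex")


def fit_ellipse(points: Sequence[Sequence[float]] | np.ndarray) -> EllipseModel:
    """Direct least-squares conic fit with ellipse constraint.

    ``points`` are (x, y) pixel coordinates of the boundary. Requires at
    least 6 non-collinear points; raises ``ValueError`` otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (x, y)")
    if len(pts) < 6:
        raise ValueError(f"need at least 6 boundary points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError("boundary points are collinear; cannot fit an ellipse")

    # center and scale for conditioning; the direct conic fit is not
    # translation-invariant numerically
    shift = pts.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1)))) or 1.0
    norm = centered / scale

    # the direct conic solve can hit eigen-degeneracies on exact data;
    # retry in a slightly rotated frame and rotate the result back
    last_exc: Exception | None = None
    for rot in (0.0, 0.1, 0.37, 0.71):
        c, s = math.cos(rot), math.sin(rot)
        rotated = norm @ np.array([[c, s], [-s, c]]).T
        try:
            model, params = _fit_conic(rotated)
        except (TypeError, np.linalg.LinAlgError) as exc:
            last_exc = exc
            continue
        if params is None:
            continue
        xc, yc, a, b, theta = params
        if np.all(np.isfinite([xc, yc, a, b, theta])) and a > 0 and b > 0:
            rms = float(np.sqrt(np.mean(model.residuals(rotated) ** 2))) * scale
            xc, yc = np.array([[c, -s], [s, c]]) @ [xc, yc]
            theta = theta + rot
            break
    else:
        raise ValueError("degenerate input: ellipse fit failed") from last_exc
    xc, yc = np.array([xc, yc]) * scale + shift
    a, b = a * scale, b * scale
    return EllipseModel(float(xc), float(yc), float(a), float(b), float(theta),
                        residual_rms=rms)


def _fit_conic(pts: np.ndarray):
    """Run the scikit-image direct ellipse fit; returns (model, params|None)."""
    if hasattr(_SkimageEllipseModel, "from_estimate"):
        model = _SkimageEllipseModel.from_estimate(pts)
        if not model:
            return model, None
        (xc, yc), (a, b) = model.center, model.axis_lengths
        return model, (xc, yc, a, b, model.theta)
    model = _SkimageEllipseModel()  # scikit-image < 0.26
    if not model.estimate(pts) or model.params is None:
        return model, None
    return model, tuple(model.params)


def fit_ellipse_from_mask(mask: np.ndarray) -> EllipseModel:
    """Fit the perimeter ellipse of a binary mask's longest contour."""
    from skimage.measure import find_contours

    mask = np.asarray(mask)
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour to fit")
    contour = max(contours, key=len)  # (row, col) pairs
    return fit_ellipse(contour[:, ::-1])


def scale_ellipse(ellipse: EllipseModel, f: float) -> EllipseModel:
    """Concentric ellipse with both semi-axes multiplied by ``f`` (> 0)."""
    if not f > 0:
        raise ValueError(f"scale factor must be > 0, got {f}")
    return EllipseModel(ellipse.center_x, ellipse.center_y,
                        ellipse.a * f, ellipse.b * f, ellipse.theta)


def elliptical_radius(points: np.ndarray, ellipse: EllipseModel) -> np.ndarray:
    """Per-point scale factor ``f`` placing each point on the scaled ellipse."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - ellipse.center
    ct, st = math.cos(ellipse.theta), math.sin(ellipse.theta)
    u = (d[:, 0] * ct + d[:, 1] * st) / ellipse.a
    v = (-d[:, 0] * st + d[:, 1] * ct) / ellipse.b
    return np.hypot(u, v)


def classify_points(points: Sequence[Sequence[float]] | np.ndarray,
                    ellipse: EllipseModel, f: float) -> dict[str, int]:
    """Split points into {inner, outer, outside} counts at boundary factor ``f``.

    inner: inside (or on) the scaled ellipse; outer: inside the full ellipse
    but outside the scaled one; outside: beyond the full ellipse (excluded
    from downstream ratios). Counts always sum to ``len(points)``.
    """
    if not 0 < f < 1:
        raise ValueError(f"boundary factor must satisfy 0 < f < 1, got {f}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return {"inner": 0, "outer": 0, "outside": 0}
    r = elliptical_radius(pts, ellipse)
    inner = int(np.sum(r <= f))
    outer = int(np.sum((r > f) & (r <= 1.0)))
    outside = int(np.sum(r > 1.0))
    return {"inner": inner, "outer": outer, "outside": outside}


def vertex_angle(v: Sequence[float], p1: Sequence[float],
                 p2: Sequence[float]) -> float:
    """Unsigned angle in degrees, in [0, 180], between rays v->p1 and v->p2.

    Mirrors a three-point angle tool: two rays from the middle point.
    """
    v = np.asarray(v, dtype=float)
    r1 = np.asarray(p1, dtype=float) - v
    r2 = np.asarray(p2, dtype=float) - v
    n1, n2 = np.linalg.norm(r1), np.linalg.norm(r2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length ray")
    cosang = np.clip(np.dot(r1, r2) / (n1 * n2), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def trifurrow_angles(annotation: VertexAnnotation) -> tuple[float, float, float]:
    """The three consecutive angles around a tri-furrow vertex, in degrees.

    Ordered by ray bearing; the angles sum to 360 by construction.
    """
    v = np.asarray(annotation.vertex, dtype=float)
    bearings = []
    for p in annotation.rays:
        d = np.asarray(p, dtype=float) - v
        bearings.append(math.atan2(d[1], d[0]) % (2 * math.pi))
    bearings = np.sort(np.asarray(bearings))
    if np.any(np.diff(bearings) < 1e-12) or (
            (bearings[0] + 2 * math.pi) - bearings[-1] < 1e-12):
        raise ValueError("coincident rays")
    gaps = np.diff(np.concatenate([bearings, [bearings[0] + 2 * math.pi]]))
    return tuple(float(math.degrees(g)) for g in gaps)


def estimate_ray_bearings(frame: ImageFrame, vertex: Sequence[float],
                          radius_px: float, n_rays: int = 3,
                          n_theta: int = 720) -> np.ndarray:
    """Estimate bearings (radians) of bright ridges radiating from a vertex.

    Samples mean intensity on circles of radius ``radius_px/2 .. radius_px``
    about the vertex and takes the ``n_rays`` dominant angular peaks, refined
    by a circular center-of-mass within +/- 10 degrees.
    """
    v = np.asarray(vertex, dtype=float)
    theta = np.arange(n_theta) * (2 * math.pi / n_theta)
    radii = np.linspace(0.5 * radius_px, radius_px, 5)
    prof = np.zeros(n_theta)
    for r in radii:
        xs = v[0] + r * np.cos(theta)
        ys = v[1] + r * np.sin(theta)
        prof += map_coordinates(frame.data, np.stack([ys, xs]), order=1, cval=0.0)
    prof /= len(radii)

    from scipy.signal import find_peaks
    tiled = np.concatenate([prof, prof, prof])
    peaks, props = find_peaks(tiled, prominence=1e-12)
    in_mid = (peaks >= n_theta) & (peaks < 2 * n_theta)
    peaks, prom = peaks[in_mid] - n_theta, props["prominences"][in_mid]
    if len(peaks) < n_rays:
        raise ValueError(f"found only {len(peaks)} ridge directions")
    top = peaks[np.argsort(prom)[::-1][:n_rays]]

    bearings = []
    half = int(round(10 / 360 * n_theta))
    for p in top:
        idx = (np.arange(p - half, p + half + 1)) % n_theta
        w = prof[idx] - prof[idx].min()
        ang = theta[idx]
        # circular mean weighted by intensity above the local floor
        c = np.sum(w * np.cos(ang)), np.sum(w * np.sin(ang))
        bearings.append(math.atan2(c[1], c[0]) % (2 * math.pi))
    return np.sort(np.asarray(bearings))


def polar_unwrap(frame: ImageFrame, ellipse: EllipseModel,
                 mode: str = "linear", n_theta: int = 360, n_r: int = 100,
                 r_min: float = 0.05, fill: float = 0.0) -> ImageFrame:
    """Unwrap the interior of an ellipse into a (radius x angle) image.

    Rows run from the cell wall (elliptical radius 1, top row) inward;
    columns are the parametric angle. ``mode`` selects linear or log spacing
    of the radial axis (log mode spans ``[r_min, 1]``). Bilinear
    interpolation, constant ``fill`` outside the image support.
    """
    if mode not in ("linear", "log"):
        raise ValueError(f"mode must be 'linear' or 'log', got {mode!r}")
    _require_ellipse_in_frame(frame, ellipse)
    if mode == "linear":
        f = np.linspace(1.0, 0.0, n_r)
    else:
        f = np.exp(np.linspace(0.0, math.log(r_min), n_r))
    t = np.arange(n_theta) * (2 * math.pi / n_theta)
    ff, tt = np.meshgrid(f, t, indexing="ij")
    ct, st = math.cos(ellipse.theta), math.sin(ellipse.theta)
    ex = ff * ellipse.a * np.cos(tt)
    ey = ff * ellipse.b * np.sin(tt)
    xs = ellipse.center_x + ex * ct - ey * st
    ys = ellipse.center_y + ex * st + ey * ct
    out = map_coordinates(frame.data, np.stack([ys, xs]), order=1, cval=fill)
    return ImageFrame(out, pixel_size=frame.pixel_size, timestamp=frame.timestamp)


def ellipse_perimeter(ellipse: EllipseModel) -> float:
    """Perimeter in px via Ramanujan's second approximation."""
    a, b = ellipse.a, ellipse.b
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def _arc_lengths(ellipse: EllipseModel, f: float, t: np.ndarray) -> np.ndarray:
    """Arc length (px) along the scaled ellipse at parameter values ``t``.

    Numerical cumulative integration of the parametric speed on a dense grid.
    """
    dense = np.linspace(0, 2 * math.pi, 8192)
    speed = f * np.hypot(ellipse.a * np.sin(dense), ellipse.b * np.cos(dense))
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (speed[1:] + speed[:-1]) * np.diff(dense))])
    return np.interp(t, dense, cum)


def ellipse_band_profile(frame: ImageFrame, ellipse: EllipseModel, f: float,
                         n_samples: int = 360, band_px: float = 3.0):
    """Mean intensity in a band normal to the scaled ellipse.

    Sampled at ``n_samples`` equally spaced parameter values; positions are
    reported as arc length in μm along the scaled ellipse. Returns a periodic
    :class:`cellfoam.foam.IntensityProfile`.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    scaled = scale_ellipse(ellipse, f)
    t = np.arange(n_samples) * (2 * math.pi / n_samples)
    on = scaled.point_at(t)  # (n, 2)
    # outward normal of the scaled ellipse at parameter t
    ct, st = math.cos(scaled.theta), math.sin(scaled.theta)
    tx = -scaled.a * np.sin(t) * ct - scaled.b * np.cos(t) * st
    ty = -scaled.a * np.sin(t) * st + scaled.b * np.cos(t) * ct
    norm = np.hypot(tx, ty)
    nx, ny = ty / norm, -tx / norm
    offsets = np.linspace(-band_px / 2, band_px / 2, max(3, int(round(band_px)) | 1))
    xs = on[:, 0][None, :] + offsets[:, None] * nx[None, :]
    ys = on[:, 1][None, :] + offsets[:, None] * ny[None, :]
    rows, cols = frame.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > cols - 1 or ys.max() > rows - 1:
        raise ValueError("sampling band exits the image")
    vals = map_coordinates(frame.data, np.stack([ys, xs]), order=1, cval=0.0)
    profile_vals = vals.mean(axis=0)
    positions_um = _arc_lengths(ellipse, f, t) * frame.pixel_size
    total_um = _arc_lengths(ellipse, f, np.array([2 * math.pi]))[0] * frame.pixel_size

    from .foam import IntensityProfile
    return IntensityProfile(positions=positions_um, values=profile_vals,
                            periodic=True, total_length=float(total_um))


def _require_ellipse_in_frame(frame: ImageFrame, ellipse: EllipseModel) -> None:
    t = np.linspace(0, 2 * math.pi, 256)
    pts = ellipse.point_at(t)
    rows, cols = frame.shape
    if (pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5
            or pts[:, 0].max() > cols - 0.5 or pts[:, 1].max() > rows - 0.5):
        raise ValueError("ellipse does not lie within the frame")


def plateau_tetrahedral_angle() -> float:
    """Angle (degrees) between centroid-to-vertex vectors of a regular
    tetrahedron — the four-film meeting angle of a minimal foam."""
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    verts -= verts.mean(axis=0)
    u, v = verts[0], verts[1]
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(math.degrees(math.acos(cosang)))


def regular_polygon_interior_angle(n: int) -> float:
    """Interior angle of a regular n-gon in degrees: (n-2)*180/n."""
    if n < 3:
        raise ValueError("a polygon needs at least 3 sides")
    return (n - 2) * 180.0 / n
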