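"""Seeded generators of synthetic microscopy scenes with ground truth.

Every generator is fully determined by its :class:`SyntheticSceneConfig`
(including the seed): the same config produces a bit-identical stack and
ground truth. Truth values are emitted in analysis units (μm, μm/s,
degrees, minutes) so estimate-vs-truth comparisons need no conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Any, Callable

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon

from .ablation import AblationEvent
from .geometry import EllipseModel, VertexAnnotation, _arc_lengths
from .image import ImageFrame, TimeLapse

__all__ = [
    "SyntheticSceneConfig",
    "GroundTruth",
    "make_foam_section",
    "make_trifurrow",
    "make_migration_movie",
    "make_recoil_movie",
    "make_tip_recoil_movie",
    "make_dissolution_movie",
    "make_ring_layer",
]


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Common imaging parameters plus per-kind scene parameters.

    Defaults mirror a confocal acquisition at 0.11 μm/px, 1 Hz, with a
    diffraction-scale Gaussian PSF.
    """

    kind: str = "generic"
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.11
    frame_interval: float = 1.0
    psf_sigma: float = 1.5
    read_noise_sd: float = 0.01
    shot_noise: bool = False
    seed: int = 0
    params: dict[str, Any] = dc_field(default_factory=dict)

    def get(self, key: str, default: Any = None) -> Any:
        return self.params.get(key, default)


@dataclass
class GroundTruth:
    kind: str
    data: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def __contains__(self, key: str) -> bool:
        return key in self.data


# ---------------------------------------------------------------------------
# rendering primitives

def _default_ellipse(shape: tuple[int, int], margin: float = 0.08) -> EllipseModel:
    rows, cols = shape
    return EllipseModel(center_x=(cols - 1) / 2, center_y=(rows - 1) / 2,
                        a=(0.5 - margin) * cols, b=(0.5 - margin) * rows * 0.92,
                        theta=0.0)


def _rasterize_segments(shape: tuple[int, int], segments, sigma: float,
                        amp: float = 1.0, step: float = 0.2) -> np.ndarray:
    """Render line segments as Gaussian-blurred ridges of crest height ~amp."""
    acc = np.zeros(shape, dtype=float)
    for (x1, y1), (x2, y2) in segments:
        length = math.hypot(x2 - x1, y2 - y1)
        n = max(2, int(math.ceil(length / step)) + 1)
        t = np.linspace(0, 1, n)
        xs = x1 + t * (x2 - x1)
        ys = y1 + t * (y2 - y1)
        _splat_bilinear(acc, xs, ys)
    img = gaussian_filter(acc, sigma)
    peak = img.max()
    if peak > 0:
        img = img * (amp / peak)
    return img


def _splat_bilinear(acc: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                    w: float = 1.0) -> None:
    rows, cols = acc.shape
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    for dx, dy, wt in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                       (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
        xi, yi = x0 + dx, y0 + dy
        ok = (xi >= 0) & (xi < cols) & (yi >= 0) & (yi < rows)
        np.add.at(acc, (yi[ok], xi[ok]), w * wt[ok])


def _render_spots(shape: tuple[int, int], centers: np.ndarray, sigma: float,
                  amp: float = 1.0) -> np.ndarray:
    """Sum of isotropic Gaussian spots (analytic, not rasterized)."""
    img = np.zeros(shape, dtype=float)
    if len(centers) == 0:
        return img
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cx, cy in np.atleast_2d(centers):
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    return img


def _add_noise(rng: np.random.Generator, img: np.ndarray,
               config: SyntheticSceneConfig) -> np.ndarray:
    out = img
    if config.shot_noise:
        gain = 200.0  # photons at unit intensity
        out = rng.poisson(np.clip(out, 0, None) * gain) / gain
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    return out


def _uniform_in_unit_disk(rng: np.random.Generator, n: int) -> np.ndarray:
    r = np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * math.pi, n)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


def _disk_to_ellipse(z: np.ndarray, ellipse: EllipseModel) -> np.ndarray:
    """Map unit-disk coordinates to image coordinates inside the ellipse."""
    ct, st = math.cos(ellipse.theta), math.sin(ellipse.theta)
    ex = z[:, 0] * ellipse.a
    ey = z[:, 1] * ellipse.b
    x = ellipse.center_x + ex * ct - ey * st
    y = ellipse.center_y + ex * st + ey * ct
    return np.stack([x, y], axis=1)


def _ellipse_to_disk(p: np.ndarray, ellipse: EllipseModel) -> np.ndarray:
    ct, st = math.cos(ellipse.theta), math.sin(ellipse.theta)
    d = p - ellipse.center
    u = (d[:, 0] * ct + d[:, 1] * st) / ellipse.a
    v = (-d[:, 0] * st + d[:, 1] * ct) / ellipse.b
    return np.stack([u, v], axis=1)


def _ellipse_polygon(ellipse: EllipseModel, n: int = 256) -> Polygon:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon(ellipse.point_at(t))


# ---------------------------------------------------------------------------
# foam cross-section

def make_foam_section(config: SyntheticSceneConfig):
    """Lloyd-relaxed Voronoi foam inside an ellipse, rendered as bright
    membrane ridges with one nuclear spot per cell centroid.

    params: n_cells (>= 8), lloyd_iters, ridge_sigma_px, membrane_amp,
    nucleus_amp.
    """
    n_cells = int(config.get("n_cells", 20))
    if n_cells < 8:
        raise ValueError("need at least 8 cells for a foam section")
    lloyd_iters = int(config.get("lloyd_iters", 3))
    ridge_sigma = float(config.get("ridge_sigma_px", 1.5))
    membrane_amp = float(config.get("membrane_amp", 1.0))
    nucleus_amp = float(config.get("nucleus_amp", 0.5))

    rng = np.random.default_rng(config.seed)
    ellipse = config.get("ellipse") or _default_ellipse(config.shape)
    # sanity: cells must fit at the stated ridge thickness
    mean_diam = math.sqrt(4 * ellipse.area / (math.pi * n_cells))
    if mean_diam < 4 * ridge_sigma:
        raise ValueError("too many cells for this ellipse at the stated "
                         "ridge thickness")

    z = _uniform_in_unit_disk(rng, n_cells) * 0.92
    epoly = _ellipse_polygon(ellipse)
    seeds = _disk_to_ellipse(z, ellipse)
    for _ in range(lloyd_iters):
        vor = _voronoi_with_mirrors(seeds, ellipse)
        seeds = np.array([
            _region_polygon(vor, i, epoly).centroid.coords[0]
            for i in range(len(seeds))
        ])
    vor = _voronoi_with_mirrors(seeds, ellipse)

    polygons = [_region_polygon(vor, i, epoly) for i in range(len(seeds))]
    areas_px = np.array([p.area for p in polygons])
    centroids = np.array([p.centroid.coords[0] for p in polygons])
    eq_diam_um = np.sqrt(4 * areas_px / math.pi) * config.pixel_size

    segments, vertex_info = _voronoi_edges_and_vertices(vor, len(seeds), ellipse)
    boundary = _ellipse_boundary_segments(ellipse)
    membrane = _rasterize_segments(config.shape, segments + boundary,
                                   ridge_sigma, amp=membrane_amp)
    nuclei = _render_spots(config.shape, centroids, config.psf_sigma,
                           amp=nucleus_amp)
    img = _add_noise(rng, membrane + nuclei, config)
    frame = ImageFrame(img, pixel_size=config.pixel_size)

    truth = GroundTruth("foam_section", {
        "ellipse": ellipse,
        "seeds": seeds,
        "cell_centroids": centroids,
        "cell_equivalent_diameters_um": eq_diam_um,
        "vertices": vertex_info,  # list of (xy, bearings_rad)
        "segments": segments,
        "noiseless": membrane + nuclei,
    })
    return frame, truth


def _voronoi_with_mirrors(seeds: np.ndarray, ellipse: EllipseModel) -> Voronoi:
    """Voronoi of the seeds plus their reflections across the ellipse
    boundary (in normalized-disk space), which bounds every interior cell."""
    z = _ellipse_to_disk(seeds, ellipse)
    r = np.linalg.norm(z, axis=1)
    r = np.clip(r, 1e-6, None)
    mirrored = z / r[:, None] * (2 - r)[:, None]
    pts = np.vstack([seeds, _disk_to_ellipse(mirrored, ellipse)])
    return Voronoi(pts)


def _region_polygon(vor: Voronoi, i: int, epoly: Polygon) -> Polygon:
    region = vor.regions[vor.point_region[i]]
    if -1 in region or len(region) < 3:
        return Point(vor.points[i]).buffer(1.0)  # degenerate fallback
    poly = Polygon(vor.vertices[region])
    clipped = poly.intersection(epoly)
    if clipped.is_empty or clipped.area == 0:
        return Point(vor.points[i]).buffer(1.0)
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    return clipped


def _voronoi_edges_and_vertices(vor: Voronoi, n_interior: int,
                                ellipse: EllipseModel):
    from .geometry import elliptical_radius

    epoly = _ellipse_polygon(ellipse)
    segments = []
    incident: dict[int, list[int]] = {}
    for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p1 >= n_interior and p2 >= n_interior:
            continue
        if -1 in verts:
            continue
        v1, v2 = verts
        a, b = vor.vertices[v1], vor.vertices[v2]
        line = LineString([a, b]).intersection(epoly)
        if line.is_empty or line.length == 0:
            continue
        if line.geom_type == "MultiLineString":
            line = max(line.geoms, key=lambda g: g.length)
        coords = np.asarray(line.coords)
        segments.append((tuple(coords[0]), tuple(coords[-1])))
        if p1 < n_interior and p2 < n_interior:  # internal junction edges only
            incident.setdefault(v1, []).append(v2)
            incident.setdefault(v2, []).append(v1)

    vertex_info = []
    for v, neighbors in incident.items():
        if len(neighbors) != 3:
            continue
        xy = vor.vertices[v]
        if elliptical_radius(xy[None], ellipse)[0] > 0.95:
            continue
        bearings = np.sort([
            math.atan2(*(vor.vertices[n] - xy)[::-1]) % (2 * math.pi)
            for n in neighbors
        ])
        vertex_info.append((tuple(xy), tuple(bearings)))
    return segments, vertex_info


def _ellipse_boundary_segments(ellipse: EllipseModel, n: int = 180):
    t = np.linspace(0, 2 * math.pi, n + 1)
    pts = ellipse.point_at(t)
    return [(tuple(pts[i]), tuple(pts[i + 1])) for i in range(n)]


# ---------------------------------------------------------------------------
# artificial tri-furrows

def make_trifurrow(angles_deg=(120.0, 120.0, 120.0), thickness_px: float = 5.0,
                   length_px: float = 40.0, noise: float = 0.0, seed: int = 0,
                   base_bearing_deg: float = 0.0,
                   shape: tuple[int, int] | None = None,
                   pixel_size: float = 0.11):
    """Three bright ridges from a central vertex at consecutive angular gaps
    ``angles_deg`` (must sum to 360). Truth is the vertex annotation."""
    angles = np.asarray(angles_deg, dtype=float)
    if len(angles) != 3 or abs(angles.sum() - 360.0) > 1e-6:
        raise ValueError("the three angles must sum to 360 degrees")
    if shape is None:
        side = int(math.ceil(2 * length_px + 6 * thickness_px))
        shape = (side, side)
    cx, cy = (shape[1] - 1) / 2, (shape[0] - 1) / 2
    bearings = math.radians(base_bearing_deg) + np.radians(
        np.concatenate([[0.0], np.cumsum(angles[:-1])]))
    endpoints = [(cx + length_px * math.cos(b), cy + length_px * math.sin(b))
                 for b in bearings]
    segments = [((cx, cy), ep) for ep in endpoints]
    img = _rasterize_segments(shape, segments, sigma=thickness_px / 2.0, amp=1.0)
    rng = np.random.default_rng(seed)
    if noise > 0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    frame = ImageFrame(img, pixel_size=pixel_size)
    truth = GroundTruth("trifurrow", {
        "annotation": VertexAnnotation(vertex=(cx, cy), rays=tuple(endpoints)),
        "bearings_rad": tuple(float(b % (2 * math.pi)) for b in bearings),
        "angles_deg": tuple(float(a) for a in angles),
    })
    return frame, truth


# ---------------------------------------------------------------------------
# cortical migration movie

def make_migration_movie(config: SyntheticSceneConfig):
    """Nuclei uniform in an ellipse whose radial coordinate is transiently
    multiplied by a Gaussian pulse ``rho(t) = 1 + A exp(-(t-t0)^2/2 s^2)``
    (clipped to the ellipse), rendered as PSF-blurred spots.

    params: n_nuclei (>= 10), n_frames, pulse_amplitude A, pulse_t0_min,
    pulse_sigma_min. ``frame_interval`` is in seconds; truth times are
    reported in minutes.
    """
    n_nuclei = int(config.get("n_nuclei", 60))
    if n_nuclei < 10:
        raise ValueError("need at least 10 nuclei")
    n_frames = int(config.get("n_frames", 21))
    amp = float(config.get("pulse_amplitude", 0.25))
    sigma_t = float(config.get("pulse_sigma_min", 5.0))
    interval_min = config.frame_interval / 60.0
    t0 = float(config.get("pulse_t0_min", (n_frames - 1) / 2 * interval_min))

    rng = np.random.default_rng(config.seed)
    ellipse = config.get("ellipse") or _default_ellipse(config.shape)
    z = _uniform_in_unit_disk(rng, n_nuclei)
    r = np.linalg.norm(z, axis=1)
    r = np.clip(r, 1e-9, None)
    unit = z / r[:, None]

    times_min = np.arange(n_frames) * interval_min
    frames = np.empty((n_frames, *config.shape))
    centroids = np.empty((n_frames, n_nuclei, 2))
    for k, t in enumerate(times_min):
        rho = 1 + amp * math.exp(-((t - t0) ** 2) / (2 * sigma_t ** 2))
        rk = np.clip(r * rho, 0, 0.98)
        pts = _disk_to_ellipse(unit * rk[:, None], ellipse)
        centroids[k] = pts
        img = _render_spots(config.shape, pts, config.psf_sigma, amp=1.0)
        frames[k] = _add_noise(rng, img, config)

    stack = TimeLapse(frames, pixel_size=config.pixel_size,
                      times=np.arange(n_frames) * config.frame_interval)
    truth = GroundTruth("migration", {
        "ellipse": ellipse,
        "centroids_px": centroids,
        "times_min": times_min,
        "pulse_t0_min": t0,
        "pulse_amplitude": amp,
        "pulse_sigma_min": sigma_t,
    })
    return stack, truth


# ---------------------------------------------------------------------------
# ablation recoil movie

def _default_recoil_profile(d_peak_um: float) -> Callable[[np.ndarray], np.ndarray]:
    def g(d_um: np.ndarray) -> np.ndarray:
        x = np.asarray(d_um, dtype=float) / d_peak_um
        return x * np.exp(1 - x)
    return g


def make_recoil_movie(config: SyntheticSceneConfig):
    """Filamentous texture advected outward from an ablation site with an
    exponentially decaying speed, with blank frames during the ablation gap.

    Velocity: ``v(p, t) = v0 exp(-t/tau) g(|p - A|) r_hat`` (μm/s), with
    ``g(0) = 0`` at the cut; an optional negative "repair" phase follows
    ``t_repair``. params: v0_um_s, tau_s, d_peak_um (or a custom profile
    ``g``), n_pre, n_blank, n_post, ablation_xy, repair_t_s,
    repair_v0_um_s, repair_tau_s.
    """
    v0 = float(config.get("v0_um_s", 0.2))
    tau = float(config.get("tau_s", 4.0))
    d_peak = float(config.get("d_peak_um", 3.0))
    g = config.get("g") or _default_recoil_profile(d_peak)
    n_pre = int(config.get("n_pre", 4))
    n_blank = int(config.get("n_blank", 2))
    n_post = int(config.get("n_post", 20))
    repair_t = config.get("repair_t_s")
    repair_v0 = float(config.get("repair_v0_um_s", 0.0))
    repair_tau = float(config.get("repair_tau_s", 5.0))

    rows, cols = config.shape
    ax, ay = config.get("ablation_xy", ((cols - 1) / 2, (rows - 1) / 2))
    dt = config.frame_interval

    # unmeasurable-by-design guard: one-step displacement vs PIV window
    max_disp_px = (abs(v0) + abs(repair_v0)) * dt / config.pixel_size
    window = float(config.get("piv_window_px", 32))
    if max_disp_px > window / 2:
        raise ValueError("per-frame displacement exceeds half the PIV window")

    rng = np.random.default_rng(config.seed)
    white = rng.normal(size=config.shape)
    texture = gaussian_filter(white, 1.0) - gaussian_filter(white, 4.0)
    texture = (texture - texture.min()) / (texture.max() - texture.min())

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    d_px = np.hypot(xx - ax, yy - ay)
    d_um = d_px * config.pixel_size
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(d_px > 0, (xx - ax) / d_px, 0.0)
        ry = np.where(d_px > 0, (yy - ay) / d_px, 0.0)
    g_map = g(d_um)

    n_frames = n_pre + n_blank + n_post
    times = np.arange(n_frames) * dt
    t_start = times[n_pre] - 0.5 * dt  # ablation begins after the last pre frame
    t_end = times[n_pre + n_blank - 1] + 0.5 * dt if n_blank else t_start
    blank_idx = tuple(range(n_pre, n_pre + n_blank))

    frames = np.empty((n_frames, rows, cols))
    current = texture.copy()
    speed_curve = np.zeros(n_frames)  # true |v| scale at each frame time
    for k in range(n_frames):
        t = times[k]
        if k > 0:
            # advect from the previous frame time with the mid-step velocity
            tm = 0.5 * (times[k - 1] + t)
            scale = _recoil_speed(tm, t_start, v0, tau, repair_t,
                                  repair_v0, repair_tau)
            disp_px = scale * g_map * dt / config.pixel_size
            src_x = xx - disp_px * rx
            src_y = yy - disp_px * ry
            current = map_coordinates(current, [src_y, src_x], order=1,
                                      mode="nearest")
        speed_curve[k] = _recoil_speed(t, t_start, v0, tau, repair_t,
                                       repair_v0, repair_tau)
        if k in blank_idx:
            frames[k] = _add_noise(rng, np.zeros(config.shape), config)
        else:
            frames[k] = _add_noise(rng, current, config)

    stack = TimeLapse(frames, pixel_size=config.pixel_size, times=times)
    event = AblationEvent(point=(ax, ay), start=float(t_start),
                          end=float(t_end), blank_frames=blank_idx)
    truth = GroundTruth("recoil", {
        "v0_um_s": v0, "tau_s": tau, "d_peak_um": d_peak, "g": g,
        "speed_curve_um_s": speed_curve, "times_s": times,
        "ablation": event, "texture": texture,
    })
    return stack, event, truth


def _recoil_speed(t: float, t_start: float, v0: float, tau: float,
                  repair_t, repair_v0: float, repair_tau: float) -> float:
    if t < t_start:
        return 0.0
    v = v0 * math.exp(-(t - t_start) / tau)
    if repair_t is not None and t >= repair_t:
        v -= repair_v0 * math.exp(-(t - repair_t) / repair_tau)
    return v


# ---------------------------------------------------------------------------
# receding-tip movie

def make_tip_recoil_movie(config: SyntheticSceneConfig):
    """Two Gaussian furrow tips on a horizontal line separating as
    ``D(t) = D0 + A (1 - exp(-t/tau))`` μm.

    params: D0_um, A_um, tau_s, n_frames, tip_amp. Frames where the tips
    are closer than twice the PSF sigma are flagged unresolvable in truth.
    """
    d0 = float(config.get("D0_um", 2.0))
    amp = float(config.get("A_um", 2.0))
    tau = float(config.get("tau_s", 5.0))
    n_frames = int(config.get("n_frames", 40))
    tip_amp = float(config.get("tip_amp", 1.0))

    rows, cols = config.shape
    cx, cy = (cols - 1) / 2, (rows - 1) / 2
    times = np.arange(n_frames) * config.frame_interval
    d_um = d0 + amp * (1 - np.exp(-times / tau))
    half_px = d_um / 2 / config.pixel_size
    if np.any(cx + half_px.max() > cols - 3 * config.psf_sigma):
        raise ValueError("tips exit the frame; enlarge the image or shrink A")

    rng = np.random.default_rng(config.seed)
    frames = np.empty((n_frames, rows, cols))
    for k in range(n_frames):
        centers = np.array([[cx - half_px[k], cy], [cx + half_px[k], cy]])
        img = _render_spots(config.shape, centers, config.psf_sigma, amp=tip_amp)
        frames[k] = _add_noise(rng, img, config)

    stack = TimeLapse(frames, pixel_size=config.pixel_size, times=times)
    truth = GroundTruth("tip_recoil", {
        "D0_um": d0, "A_um": amp, "tau_s": tau,
        "distance_um": d_um, "times_s": times,
        "line": ((cx - cols * 0.45, cy), (cx + cols * 0.45, cy)),
        "resolvable": d_um / config.pixel_size >= 2 * config.psf_sigma,
    })
    return stack, truth


# ---------------------------------------------------------------------------
# network dissolution movie

def make_dissolution_movie(config: SyntheticSceneConfig):
    """Foam scene whose ridge contrast decays toward the spatial mean after
    a treatment onset and recovers after washout.

    params: n_frames, onset_frame, offset_frame, diss_tau_frames, alpha_min,
    plus the foam-section params. Truth carries the contrast curve alpha(t).
    """
    n_frames = int(config.get("n_frames", 30))
    onset = int(config.get("onset_frame", 10))
    offset = config.get("offset_frame", 20)
    tau_f = float(config.get("diss_tau_frames", 2.0))
    alpha_min = float(config.get("alpha_min", 0.05))
    if not (0 <= onset < n_frames):
        raise ValueError("onset frame out of range")
    if offset is not None and not (onset < offset <= n_frames):
        raise ValueError("offset frame out of range")

    base_cfg = SyntheticSceneConfig(
        kind="foam_section", shape=config.shape, pixel_size=config.pixel_size,
        psf_sigma=config.psf_sigma, read_noise_sd=0.0, seed=config.seed,
        params=config.params)
    frame0, foam_truth = make_foam_section(base_cfg)
    base = foam_truth["noiseless"]
    mean = base.mean()

    alpha = np.ones(n_frames)
    for k in range(n_frames):
        if k >= onset:
            alpha[k] = alpha_min + (1 - alpha_min) * math.exp(-(k - onset) / tau_f)
        if offset is not None and k >= offset:
            recover = 1 - math.exp(-(k - offset) / tau_f)
            alpha[k] = alpha[offset - 1] + (1 - alpha[offset - 1]) * recover

    rng = np.random.default_rng(config.seed + 1)
    frames = np.empty((n_frames, *config.shape))
    for k in range(n_frames):
        img = mean + alpha[k] * (base - mean)
        frames[k] = _add_noise(rng, img, config)
    stack = TimeLapse(frames, pixel_size=config.pixel_size,
                      times=np.arange(n_frames) * config.frame_interval)
    truth = GroundTruth("dissolution", {
        "alpha": alpha, "onset_frame": onset, "offset_frame": offset,
        "foam": foam_truth,
    })
    return stack, truth


# ---------------------------------------------------------------------------
# peripheral daughter ring

def make_ring_layer(config: SyntheticSceneConfig):
    """Radial furrow segments crossing the 0.85-factor ellipse at arc
    spacings drawn around a stated mean with multiplicative jitter.

    params: n_daughters (>= 6), jitter_frac, furrow_f_range, ridge_sigma_px,
    ellipse. Spacings are rescaled to close the ring exactly; truth lists
    them in μm along the 0.85 ellipse.
    """
    n = int(config.get("n_daughters", 12))
    if n < 6:
        raise ValueError("need at least 6 daughters")
    jitter = float(config.get("jitter_frac", 0.05))
    f_lo, f_hi = config.get("furrow_f_range", (0.70, 0.995))
    ridge_sigma = float(config.get("ridge_sigma_px", 1.5))
    f_ring = float(config.get("ring_factor", 0.85))

    rng = np.random.default_rng(config.seed)
    ellipse = config.get("ellipse") or _default_ellipse(config.shape)
    total_px = _arc_lengths(ellipse, f_ring, np.array([2 * math.pi]))[0]
    total_um = total_px * config.pixel_size

    gaps = rng.normal(1.0, jitter, n)
    gaps = np.clip(gaps, 0.2, None)
    gaps = gaps / gaps.sum() * total_um  # periodic closure
    spacing_px_min = gaps.min() / config.pixel_size
    if spacing_px_min < 4 * ridge_sigma:
        raise ValueError("furrows overlap at the stated thickness")
    arcs_um = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    arcs_um = (arcs_um + rng.uniform(0, total_um)) % total_um

    # invert arc length -> parametric angle on a dense grid
    dense_t = np.linspace(0, 2 * math.pi, 8192)
    dense_s = _arc_lengths(ellipse, f_ring, dense_t) * config.pixel_size
    t_values = np.interp(np.sort(arcs_um), dense_s, dense_t)

    segments = []
    for t in t_values:
        p_in = ellipse.point_at(t, f=f_lo)
        p_out = ellipse.point_at(t, f=f_hi)
        segments.append((tuple(p_in), tuple(p_out)))
    segments += _ellipse_boundary_segments(ellipse)
    img = _rasterize_segments(config.shape, segments, ridge_sigma, amp=1.0)
    frame = ImageFrame(_add_noise(rng, img, config),
                       pixel_size=config.pixel_size)

    sorted_arcs = np.sort(arcs_um)
    spacings = np.diff(np.concatenate([sorted_arcs, [sorted_arcs[0] + total_um]]))
    truth = GroundTruth("ring_layer", {
        "ellipse": ellipse, "ring_factor": f_ring,
        "arc_positions_um": sorted_arcs,
        "spacings_um": spacings,
        "perimeter_um": float(total_um),
    })
    return frame, truth
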