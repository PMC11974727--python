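"""Laser-ablation recoil analysis: FFT cross-correlation PIV, SNR filtering,
radial velocity decomposition about the ablation site, distance/time
summaries, kymographs, and receding-tip distance curves.

Sign convention for the radial component: positive = motion away from the
ablation site (recoil), negative = motion toward it (repair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from skimage.filters import threshold_multiotsu

from .foam import IntensityProfile, detect_peaks
from .image import ImageFrame, TimeLapse
from .resampling import bootstrap_ci_mean

__all__ = [
    "AblationEvent",
    "VelocityField",
    "TipDistanceSeries",
    "piv_field",
    "filter_vectors",
    "radial_velocity",
    "summarize_radial",
    "recoil_duration",
    "top_fraction",
    "resample_stack",
    "preablation_mask",
    "kymograph",
    "tip_distance_series",
    "fit_tip_recoil",
]


@dataclass(frozen=True)
class AblationEvent:
    """Ablation site (px), its start/end times (s), and blank frame indices."""

    point: tuple[float, float]
    start: float
    end: float
    blank_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("ablation start must precede its end")


@dataclass
class VelocityField:
    """PIV vectors at window centers: locations in px, velocities in μm/s.

    Arrays are flat and aligned; ``v`` follows image coordinates (y grows
    downward). ``t`` is the time (s) assigned to the frame pair, typically
    relative to the ablation end.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    snr: np.ndarray
    dt: float
    pixel_size: float
    t: float = 0.0
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        for name in ("x", "y", "u", "v", "snr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if not (len(self.x) == len(self.y) == len(self.u)
                == len(self.v) == len(self.snr)):
            raise ValueError("vector arrays must be aligned")
        if not np.all(np.isfinite(self.u)) or not np.all(np.isfinite(self.v)):
            raise ValueError("velocities must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def take(self, mask: np.ndarray) -> "VelocityField":
        return replace(self, x=self.x[mask], y=self.y[mask], u=self.u[mask],
                       v=self.v[mask], snr=self.snr[mask], grid_shape=None)


@dataclass
class TipDistanceSeries:
    """Per-frame inter-tip distance (μm); NaN where two confident peaks were
    not found (``valid`` marks usable frames)."""

    times: np.ndarray
    distances: np.ndarray
    valid: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.valid) == 0:
            self.valid = np.isfinite(self.distances)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if np.any(self.distances[self.valid] < 0):
            raise ValueError("distances must be >= 0")


def _gauss_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """3-point Gaussian peak interpolation; 0 when the fit is ill-posed."""
    floor = 1e-12
    cm1, c0, cp1 = (max(c, floor) for c in (cm1, c0, cp1))
    denom = 2 * (math.log(cm1) + math.log(cp1) - 2 * math.log(c0))
    if denom >= 0 or not math.isfinite(denom):
        return 0.0
    return (math.log(cm1) - math.log(cp1)) / denom


def piv_field(frame_a: ImageFrame | np.ndarray, frame_b: ImageFrame | np.ndarray,
              window_px: int = 32, overlap_px: int = 16, dt: float = 1.0,
              pixel_size: float | None = None) -> VelocityField:
    """Standard FFT cross-correlation PIV between two frames.

    Per interrogation window: zero-normalized linear cross-correlation,
    integer peak plus 3-point Gaussian sub-pixel refinement in each axis.
    The displacement (px) maps to μm/s via ``pixel_size / dt``. The SNR is
    the first-to-second correlation peak ratio (second peak taken outside a
    3 px exclusion zone around the first).
    """
    a = frame_a.data if isinstance(frame_a, ImageFrame) else np.asarray(frame_a, float)
    b = frame_b.data if isinstance(frame_b, ImageFrame) else np.asarray(frame_b, float)
    if pixel_size is None:
        pixel_size = frame_a.pixel_size if isinstance(frame_a, ImageFrame) else 1.0
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if window_px < 16:
        raise ValueError("window must be at least 16 px")
    if not 0 <= overlap_px < window_px:
        raise ValueError("overlap must satisfy 0 <= overlap < window")
    rows, cols = a.shape
    if window_px > rows or window_px > cols:
        raise ValueError("window larger than frame")

    step = window_px - overlap_px
    r_starts = np.arange(0, rows - window_px + 1, step)
    c_starts = np.arange(0, cols - window_px + 1, step)
    xs, ys, us, vs, snrs = [], [], [], [], []
    half = window_px - 1
    for r0 in r_starts:
        for c0 in c_starts:
            wa = a[r0:r0 + window_px, c0:c0 + window_px]
            wb = b[r0:r0 + window_px, c0:c0 + window_px]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            corr = fftconvolve(wb, wa[::-1, ::-1], mode="full")
            dy, dx, snr = _peak_and_snr(corr, half)
            xs.append(c0 + (window_px - 1) / 2)
            ys.append(r0 + (window_px - 1) / 2)
            us.append(dx * pixel_size / dt)
            vs.append(dy * pixel_size / dt)
            snrs.append(snr)
    return VelocityField(np.array(xs), np.array(ys), np.array(us), np.array(vs),
                         np.array(snrs), dt=dt, pixel_size=pixel_size,
                         grid_shape=(len(r_starts), len(c_starts)))


def _peak_and_snr(corr: np.ndarray, center: int) -> tuple[float, float, float]:
    pr, pc = np.unravel_index(np.argmax(corr), corr.shape)
    peak1 = corr[pr, pc]
    if peak1 <= 0:
        return 0.0, 0.0, 0.0
    sub_r = sub_c = 0.0
    if 0 < pr < corr.shape[0] - 1:
        sub_r = _gauss_subpixel(corr[pr - 1, pc], peak1, corr[pr + 1, pc])
    if 0 < pc < corr.shape[1] - 1:
        sub_c = _gauss_subpixel(corr[pr, pc - 1], peak1, corr[pr, pc + 1])
    masked = corr.copy()
    r0, r1 = max(0, pr - 3), min(corr.shape[0], pr + 4)
    c0, c1 = max(0, pc - 3), min(corr.shape[1], pc + 4)
    masked[r0:r1, c0:c1] = -np.inf
    peak2 = masked.max()
    snr = float(peak1 / peak2) if peak2 > 0 else float("inf")
    return (pr + sub_r - center), (pc + sub_c - center), snr


def filter_vectors(field: VelocityField, snr_min: float = 1.3) -> VelocityField:
    """Keep vectors with nonzero magnitude that pass the SNR test."""
    if snr_min < 1:
        raise ValueError("snr_min must be >= 1")
    return field.take((field.speed > 0) & (field.snr >= snr_min))


def radial_velocity(field: VelocityField, event: AblationEvent) -> pd.DataFrame:
    """Project each vector onto the unit vector pointing away from the
    ablation site.

    Returns a DataFrame with columns ``t_s, d_um, v_rad_um_s, snr, x_px,
    y_px``; vectors located exactly at the site are skipped.
    """
    ax, ay = event.point
    dx = field.x - ax
    dy = field.y - ay
    dist_px = np.hypot(dx, dy)
    keep = dist_px > 0
    rx, ry = dx[keep] / dist_px[keep], dy[keep] / dist_px[keep]
    v_rad = field.u[keep] * rx + field.v[keep] * ry
    return pd.DataFrame({
        "t_s": field.t,
        "d_um": dist_px[keep] * field.pixel_size,
        "v_rad_um_s": v_rad,
        "snr": field.snr[keep],
        "x_px": field.x[keep],
        "y_px": field.y[keep],
    })


def summarize_radial(records: pd.DataFrame,
                     distance_bins_um: np.ndarray | float = 1.0,
                     time_bins_s: np.ndarray | float | None = None,
                     ci_level: float = 0.99, n_boot: int = 2000,
                     seed: int | None = 0) -> pd.DataFrame:
    """Mean radial velocity per (distance, time) bin with bootstrap CIs.

    Scalar bin arguments are treated as bin widths starting at 0. Empty
    bins appear with NaN mean and ``n = 0`` rather than being dropped.
    """
    if len(records) == 0:
        raise ValueError("no radial records to summarize")
    d_edges = _edges(records["d_um"].to_numpy(), distance_bins_um)
    if time_bins_s is None:
        t_vals = np.unique(records["t_s"].to_numpy())
        width = float(np.min(np.diff(t_vals))) if len(t_vals) > 1 else 1.0
        time_bins_s = width
    t_edges = _edges(records["t_s"].to_numpy(), time_bins_s, start_at_min=True)

    rng = np.random.default_rng(seed)
    rows = []
    d_idx = np.clip(np.digitize(records["d_um"], d_edges) - 1, 0, len(d_edges) - 2)
    t_idx = np.clip(np.digitize(records["t_s"], t_edges) - 1, 0, len(t_edges) - 2)
    v = records["v_rad_um_s"].to_numpy()
    for ti in range(len(t_edges) - 1):
        for di in range(len(d_edges) - 1):
            sel = v[(d_idx == di) & (t_idx == ti)]
            row = {"t_lo_s": t_edges[ti], "t_hi_s": t_edges[ti + 1],
                   "d_lo_um": d_edges[di], "d_hi_um": d_edges[di + 1],
                   "n": len(sel)}
            if len(sel) == 0:
                row.update(mean_v_um_s=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                           defined=False)
            elif len(sel) == 1:
                row.update(mean_v_um_s=float(sel[0]), ci_lo=float(sel[0]),
                           ci_hi=float(sel[0]), defined=True)
            else:
                lo, hi = bootstrap_ci_mean(sel, level=ci_level, n_boot=n_boot,
                                           seed=int(rng.integers(2 ** 31)))
                row.update(mean_v_um_s=float(sel.mean()), ci_lo=lo, ci_hi=hi,
                           defined=True)
            rows.append(row)
    return pd.DataFrame(rows)


def _edges(values: np.ndarray, bins, start_at_min: bool = False) -> np.ndarray:
    if np.ndim(bins) > 0:
        return np.asarray(bins, dtype=float)
    width = float(bins)
    lo = math.floor(values.min() / width) * width if start_at_min else 0.0
    hi = values.max()
    n = max(1, int(math.ceil((hi - lo) / width + 1e-9)))
    return lo + width * np.arange(n + 1)


def recoil_duration(summary: pd.DataFrame) -> float:
    """Detectable recoil duration from a time-binned radial summary.

    The upper time edge of the last bin whose bootstrap CI lies strictly
    above zero; 0.0 when no bin shows significant outward motion.
    """
    pos = summary[(summary["defined"]) & (summary["ci_lo"] > 0)
                  & (summary["t_hi_s"] > 0)]
    if len(pos) == 0:
        return 0.0
    return float(pos["t_hi_s"].max())


def top_fraction(field: VelocityField, q: float = 0.10) -> VelocityField:
    """Vectors whose speed reaches the top-``q`` quantile; ties included."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if len(field) == 0:
        return field
    thr = np.quantile(field.speed, 1 - q)
    return field.take(field.speed >= thr)


def resample_stack(stack: TimeLapse, interval_s: float) -> TimeLapse:
    """Keep the frame nearest to each point of a regular resampling grid.

    Timestamps are preserved from the originals; no frame is duplicated.
    The interval must not be finer than the native sampling.
    """
    times = stack.times
    native = float(np.min(np.diff(times))) if len(times) > 1 else interval_s
    if interval_s < native - 1e-9:
        raise ValueError("resampling interval finer than native sampling")
    grid = np.arange(times[0], times[-1] + 1e-9, interval_s)
    picked: list[int] = []
    for g in grid:
        i = int(np.argmin(np.abs(times - g)))
        if not picked or i != picked[-1]:
            picked.append(i)
    return stack.subset(picked)


def preablation_mask(stack: TimeLapse, event: AblationEvent,
                     n_classes: int = 3) -> np.ndarray:
    """Mask of the cellularization structures from pre-ablation frames.

    Sums all frames before the ablation start and applies multi-level Otsu;
    the mask is the union of classes above background.
    """
    pre = stack.frames[stack.times < event.start]
    if len(pre) == 0:
        raise ValueError("no frames before ablation start")
    total = pre.sum(axis=0)
    try:
        thresholds = threshold_multiotsu(total, classes=n_classes)
    except ValueError as exc:
        raise ValueError("pre-ablation sum has no structure to threshold") from exc
    return total > thresholds[0]


def _band_coordinates(line_segment, width_px: float, spacing: float = 1.0):
    (x1, y1), (x2, y2) = line_segment
    p1 = np.array([x1, y1], dtype=float)
    p2 = np.array([x2, y2], dtype=float)
    seg = p2 - p1
    length = float(np.linalg.norm(seg))
    if length == 0:
        raise ValueError("line segment has zero length")
    n_pos = int(math.floor(length / spacing)) + 1
    tpar = np.linspace(0, 1, n_pos)
    direction = seg / length
    normal = np.array([-direction[1], direction[0]])
    n_w = max(1, int(round(width_px)))
    offs = (np.arange(n_w) - (n_w - 1) / 2)
    base = p1[None, :] + tpar[:, None] * seg[None, :]
    pts = base[None, :, :] + offs[:, None, None] * normal[None, None, :]
    return pts, tpar * length  # (n_w, n_pos, 2), positions in px


def kymograph(stack: TimeLapse, line_segment, width_px: float = 20.0) -> ImageFrame:
    """Time (rows) x position-along-segment (columns) image; each cell is
    the *sum* of intensity across the band normal to the segment."""
    pts, _ = _band_coordinates(line_segment, width_px)
    _require_band_inside(stack.frames[0].shape, pts)
    out = np.empty((len(stack), pts.shape[1]))
    coords = np.stack([pts[..., 1], pts[..., 0]])  # (2, n_w, n_pos)
    for i, frame in enumerate(stack.frames):
        vals = map_coordinates(frame, coords.reshape(2, -1), order=1, cval=0.0)
        out[i] = vals.reshape(pts.shape[:2]).sum(axis=0)
    return ImageFrame(out, pixel_size=stack.pixel_size, timestamp=stack.times[0])


def _require_band_inside(shape, pts) -> None:
    rows, cols = shape
    if (pts[..., 0].min() < -0.5 or pts[..., 1].min() < -0.5
            or pts[..., 0].max() > cols - 0.5 or pts[..., 1].max() > rows - 0.5):
        raise ValueError("band exits the frame")


def tip_distance_series(stack: TimeLapse, line_segment, width_px: float = 10.0,
                        min_prominence_frac: float = 0.10,
                        min_distance_um: float = 0.5) -> TipDistanceSeries:
    """Distance between the two receding furrow tips over time.

    Per frame: the *mean* intensity profile across the band along the
    segment, peak detection, then the separation (μm) of the two most
    prominent peaks. Frames without two confident peaks are flagged
    (NaN, ``valid=False``) and left out of downstream fits.
    """
    pts, pos_px = _band_coordinates(line_segment, width_px)
    _require_band_inside(stack.frames[0].shape, pts)
    coords = np.stack([pts[..., 1], pts[..., 0]])
    positions_um = pos_px * stack.pixel_size
    dists = np.full(len(stack), np.nan)
    for i, frame in enumerate(stack.frames):
        vals = map_coordinates(frame, coords.reshape(2, -1), order=1, cval=0.0)
        profile_vals = vals.reshape(pts.shape[:2]).mean(axis=0)
        prof = IntensityProfile(positions=positions_um, values=profile_vals)
        if prof.values.max() == prof.values.min():
            continue
        peaks = detect_peaks(prof, min_prominence_frac=min_prominence_frac,
                             min_distance_um=min_distance_um)
        if len(peaks) < 2:
            continue
        top2 = np.argsort(peaks.prominences)[::-1][:2]
        p = np.sort(peaks.positions[top2])
        dists[i] = p[1] - p[0]
    return TipDistanceSeries(times=stack.times.copy(), distances=dists)


def fit_tip_recoil(series: TipDistanceSeries,
                   t0: float | None = None) -> dict[str, float]:
    """Least-squares fit of ``D(t) = D0 + A * (1 - exp(-(t - t0)/tau))``.

    ``t0`` defaults to the first valid time. Returns the fitted parameters
    plus the RMS residual.
    """
    ok = series.valid
    if ok.sum() < 4:
        raise ValueError("need at least 4 valid frames to fit the recoil")
    t = series.times[ok]
    d = series.distances[ok]
    if t0 is None:
        t0 = float(t[0])
    tt = t - t0

    def model(ts, d0, amp, tau):
        return d0 + amp * (1 - np.exp(-ts / tau))

    span = max(d.max() - d.min(), 1e-6)
    p0 = (float(d[0]), float(span), max(float(tt[-1]) / 3, 1e-3))
    popt, _ = curve_fit(model, tt, d, p0=p0, maxfev=20000)
    resid = d - model(tt, *popt)
    return {"D0": float(popt[0]), "A": float(popt[1]), "tau": float(popt[2]),
            "t0": float(t0), "rms": float(np.sqrt(np.mean(resid ** 2)))}
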