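"""Nuclear segmentation and the cortical nuclear ratio time series.

The cortical nuclear ratio is the count of nuclei in the outer donut of a
fitted sporangium ellipse divided by the count in the inner disk; with the
equal-area boundary it is ~1 under uniform placement and rises during
cortical migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_multiotsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .geometry import EllipseModel, classify_points
from .image import ImageFrame

__all__ = [
    "NucleusSet",
    "CorticalRatio",
    "CorticalRatioSeries",
    "segment_nuclei",
    "cortical_ratio",
    "align_to_peak",
    "loess_smooth",
]


@dataclass(frozen=True)
class NucleusSet:
    """Segmented nuclei of one frame: centroids (x, y in px) and areas (px^2)."""

    frame_index: int
    centroids: np.ndarray  # (n, 2)
    areas: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        a = np.asarray(self.areas, dtype=float).reshape(-1)
        if len(c) != len(a):
            raise ValueError("centroids and areas must match in length")
        if np.any(a <= 0):
            raise ValueError("areas must be positive")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "areas", a)

    def __len__(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class CorticalRatio:
    n_inner: int
    n_outer: int

    @property
    def defined(self) -> bool:
        return self.n_inner > 0

    @property
    def value(self) -> float:
        """outer/inner; NaN (flagged undefined) when the inner disk is empty."""
        if not self.defined:
            return float("nan")
        return self.n_outer / self.n_inner


@dataclass
class CorticalRatioSeries:
    """Per-frame ratios on a strictly increasing time axis (minutes).

    Undefined ratios are retained as NaN gaps rather than dropped, so peak
    alignment and smoothing can treat them explicitly.
    """

    times: np.ndarray  # minutes
    ratios: np.ndarray  # unitless, NaN where undefined
    sporangium_id: str = ""
    peak_index: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times.shape != self.ratios.shape:
            raise ValueError("times and ratios must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.ratios[np.isfinite(self.ratios)] < 0):
                raise ValueError("ratios must be >= 0 where defined")


def segment_nuclei(frame: ImageFrame, min_area_px: float = 4.0,
                   n_threshold_classes: int = 3,
                   marker_min_distance: int = 5) -> NucleusSet:
    """Segment bright nuclear spots by multi-Otsu + watershed.

    Foreground is the brightest of ``n_threshold_classes`` Otsu classes;
    touching objects are split by marker-controlled watershed on the
    distance transform (markers = local distance maxima separated by at
    least ``marker_min_distance`` px). Objects below ``min_area_px`` are
    discarded. Centroids are intensity-weighted. An unstructured (e.g.
    all-zero) frame yields an empty set.
    """
    data = frame.data
    try:
        thresholds = threshold_multiotsu(data, classes=n_threshold_classes)
    except ValueError:
        return NucleusSet(0, np.empty((0, 2)), np.empty(0))
    fg = data > thresholds[-1]
    if not fg.any():
        return NucleusSet(0, np.empty((0, 2)), np.empty(0))

    distance = ndi.distance_transform_edt(fg)
    peak_idx = peak_local_max(distance, min_distance=marker_min_distance,
                              labels=fg, exclude_border=False)
    markers = np.zeros(data.shape, dtype=np.int32)
    markers[tuple(peak_idx.T)] = np.arange(1, len(peak_idx) + 1)
    labels = watershed(-distance, markers=markers, mask=fg)

    centroids, areas = [], []
    for rp in regionprops(labels, intensity_image=data):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid_weighted
        centroids.append((cx, cy))
        areas.append(rp.area)
    if not centroids:
        return NucleusSet(0, np.empty((0, 2)), np.empty(0))
    return NucleusSet(0, np.asarray(centroids), np.asarray(areas, dtype=float))


def cortical_ratio(nuclei: NucleusSet, ellipse: EllipseModel,
                   f: float = 0.70) -> CorticalRatio:
    """Outer-donut / inner-disk nuclear count at boundary factor ``f``.

    Nuclei outside the fitted ellipse are excluded. An empty inner disk
    flags the ratio undefined (NaN) instead of raising.
    """
    if len(nuclei) == 0:
        return CorticalRatio(0, 0)
    counts = classify_points(nuclei.centroids, ellipse, f)
    return CorticalRatio(counts["inner"], counts["outer"])


def align_to_peak(series: CorticalRatioSeries,
                  median_prefilter: bool = False) -> CorticalRatioSeries:
    """Shift times so the global maximum ratio sits at t = 0.

    Ties break toward the earliest time. With ``median_prefilter`` the peak
    is located on a 3-point running median (NaN-aware) to resist
    single-frame segmentation glitches; the returned ratios are untouched.
    """
    r = series.ratios
    if not np.any(np.isfinite(r)):
        raise ValueError("cannot align: all ratios are undefined")
    search = r
    if median_prefilter and len(r) >= 3:
        padded = np.concatenate([r[:1], r, r[-1:]])
        stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
        search = np.nanmedian(stacked, axis=0)
    peak = int(np.nanargmax(search))
    return CorticalRatioSeries(times=series.times - series.times[peak],
                               ratios=r.copy(),
                               sporangium_id=series.sporangium_id,
                               peak_index=peak)


def loess_smooth(series: CorticalRatioSeries, span: float = 0.2,
                 ci_level: float = 0.99):
    """Locally weighted linear regression with tricube weights.

    Each point is fit on its nearest ``ceil(span * n)`` neighbors; the
    pointwise CI at ``ci_level`` comes from the local fit's standard error
    with a residual variance pooled across the curve. NaN (undefined)
    ratios are skipped. Returns ``(times, fitted, lo, hi)`` over the
    defined samples.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    ok = np.isfinite(series.ratios)
    x = series.times[ok]
    y = series.ratios[ok]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 defined points to smooth")
    k = int(np.ceil(span * n))
    if k < 3:
        raise ValueError("span too small: window must cover >= 3 points")

    fitted = np.empty(n)
    se_unit = np.empty(n)  # SE of the fit per unit residual SD
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        w = np.clip(w, 0, None)
        X = np.stack([np.ones(k), x[idx] - x[i]], axis=1)
        W = w[:, None]
        XtWX = X.T @ (W * X)
        XtW = X.T * w
        beta, *_ = np.linalg.lstsq(XtWX, XtW @ y[idx], rcond=None)
        fitted[i] = beta[0]
        # equivalent-kernel row for the intercept at x[i]
        l = np.linalg.lstsq(XtWX, XtW, rcond=None)[0][0]
        se_unit[i] = np.sqrt(np.sum(l ** 2))

    resid = y - fitted
    sigma = np.sqrt(np.sum(resid ** 2) / max(n - 2, 1))
    from scipy.stats import norm
    z = norm.ppf(0.5 + ci_level / 2)
    half = z * sigma * se_unit
    return x, fitted, fitted - half, fitted + half
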