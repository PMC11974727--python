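"""Daughter-size estimation from membrane intensity peaks and
co-occurrence texture dynamics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .image import ImageFrame

__all__ = [
    "IntensityProfile",
    "PeakSet",
    "TextureSeries",
    "detect_peaks",
    "daughter_diameters",
    "coefficient_of_variation",
    "glcm_asm",
    "glcm_matrix",
    "relative_homogeneity",
]

#: Unit pixel offsets at 0, 45, 90, 135 degrees, as (drow, dcol).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class IntensityProfile:
    """A 1D line scan: positions in μm (strictly increasing) and intensities.

    ``periodic`` profiles wrap around; ``total_length`` is then the full
    closed length (the perimeter), which exceeds the last sample position.
    """

    positions: np.ndarray
    values: np.ndarray
    periodic: bool = False
    total_length: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ValueError("positions and values must be matching 1D arrays")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.periodic and self.total_length is None:
            raise ValueError("periodic profiles must state their total length")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class PeakSet:
    """Detected peak positions (μm, sorted) with their prominences."""

    positions: np.ndarray
    prominences: np.ndarray
    periodic: bool = False
    support_length: float | None = None

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class TextureSeries:
    """ASM values over time with a pre-treatment reference.

    ``relative`` is asm / asm[reference_index]; the reference maps to 1
    exactly. A relative value of 1.75 reads as a 75% increase in homogeneity.
    """

    times: np.ndarray
    asm: np.ndarray
    reference_index: int
    relative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.asm = np.asarray(self.asm, dtype=float)
        ref = self.asm[self.reference_index]
        if not ref > 0:
            raise ValueError("reference ASM must be > 0")
        if np.any(self.asm <= 0) or np.any(self.asm > 1 + 1e-12):
            raise ValueError("ASM values must lie in (0, 1]")
        self.relative = self.asm / ref
        self.relative[self.reference_index] = 1.0


def detect_peaks(profile: IntensityProfile, min_prominence_frac: float = 0.10,
                 min_distance_um: float = 1.0) -> PeakSet:
    """Local maxima with prominence >= frac * dynamic range and a minimum
    spacing. Periodic profiles honor the wrap-around neighborhood."""
    vals = profile.values
    if len(vals) < 8:
        raise ValueError("profile too short (need >= 8 samples)")
    rng_v = float(vals.max() - vals.min())
    if rng_v == 0:
        return PeakSet(np.array([]), np.array([]), periodic=profile.periodic,
                       support_length=_support_length(profile))
    prominence = min_prominence_frac * rng_v
    spacing = float(np.median(np.diff(profile.positions)))
    distance = max(1, int(round(min_distance_um / spacing)))

    if profile.periodic:
        n = len(vals)
        tiled = np.concatenate([vals, vals, vals])
        idx, props = find_peaks(tiled, prominence=prominence, distance=distance)
        keep = (idx >= n) & (idx < 2 * n)
        idx, prom = idx[keep] - n, props["prominences"][keep]
    else:
        idx, props = find_peaks(vals, prominence=prominence, distance=distance)
        prom = props["prominences"]
    order = np.argsort(idx)
    return PeakSet(profile.positions[idx[order]], prom[order],
                   periodic=profile.periodic,
                   support_length=_support_length(profile))


def _support_length(profile: IntensityProfile) -> float:
    if profile.periodic:
        return float(profile.total_length)
    return float(profile.positions[-1] - profile.positions[0])


def daughter_diameters(peaks: PeakSet, periodic: bool | None = None) -> np.ndarray:
    """Consecutive peak-to-peak spacings in μm, a proxy for daughter diameter.

    For periodic profiles the closing wrap-around gap is included, so the
    number of spacings equals the number of peaks and they sum exactly to
    the profile length.
    """
    if periodic is None:
        periodic = peaks.periodic
    pos = np.asarray(peaks.positions, dtype=float)
    if len(pos) < 2:
        raise ValueError("need at least 2 peaks to measure spacings")
    gaps = np.diff(pos)
    if periodic:
        if peaks.support_length is None:
            raise ValueError("periodic spacing needs the profile length")
        closing = peaks.support_length - (pos[-1] - pos[0])
        gaps = np.concatenate([gaps, [closing]])
    return gaps


def coefficient_of_variation(values: Sequence[float]) -> float:
    """100 x sample SD / mean, in percent."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def _quantize(data: np.ndarray, mask: np.ndarray, n_levels: int,
              binning: str, value_range=None) -> np.ndarray:
    """Quantize intensities to integer levels 0..n_levels-1 (masked-out = -1).

    ``rank`` binning is equal-count on ranks (invariant to any monotone
    intensity rescaling); ``linear`` is equal-width over ``value_range``
    (default: the frame's own range). When no fixed range is given and the
    image has <= n_levels distinct values, each gets its own level so
    hand-constructed patterns survive quantization exactly.
    """
    levels = np.full(data.shape, -1, dtype=np.int64)
    vals = data[mask]
    if vals.size == 0:
        return levels
    if value_range is None:
        uniq = np.unique(vals)
        if len(uniq) <= n_levels:
            levels[mask] = np.searchsorted(uniq, vals)
            return levels
    if binning == "rank":
        from scipy.stats import rankdata
        ranks = rankdata(vals, method="average")
        q = np.floor((ranks - 1) / len(vals) * n_levels).astype(np.int64)
    elif binning == "linear":
        lo, hi = value_range if value_range is not None else (vals.min(), vals.max())
        if not hi > lo:
            levels[mask] = 0
            return levels
        q = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int64)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    levels[mask] = np.clip(q, 0, n_levels - 1)
    return levels


def glcm_matrix(frame: ImageFrame, offset: tuple[int, int] = (0, 1),
                n_levels: int = 8, mask: np.ndarray | None = None,
                binning: str = "rank", value_range=None) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix at one offset.

    ``offset`` is (drow, dcol). Pixel pairs touching masked-out pixels are
    excluded from the counting.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    data = frame.data
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    levels = _quantize(data, mask, n_levels, binning, value_range)
    dr, dc = offset
    rows, cols = data.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a >= 0) & (b >= 0)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid pixel pairs at this offset")
    counts = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    counts = counts + counts.T  # symmetric GLCM
    return counts / counts.sum()


def glcm_asm(frame: ImageFrame,
             offsets: Sequence[tuple[int, int]] | tuple[int, int] = DEFAULT_OFFSETS,
             n_levels: int = 8, mask: np.ndarray | None = None,
             binning: str = "rank", value_range=None) -> float:
    """Angular Second Moment: sum of squared GLCM entries, averaged over the
    requested offsets (default: the four unit directions). 1 for a constant
    image; 1/n_levels^2 in the i.i.d.-uniform limit."""
    if isinstance(offsets[0], int):  # a single (drow, dcol) pair
        offsets = (tuple(offsets),)
    asms = []
    for off in offsets:
        p = glcm_matrix(frame, offset=tuple(off), n_levels=n_levels,
                        mask=mask, binning=binning, value_range=value_range)
        asms.append(float(np.sum(p * p)))
    return float(np.mean(asms))


def texture_series(stack, reference_index: int, n_levels: int = 8,
                   mask: np.ndarray | None = None,
                   times: Sequence[float] | None = None) -> TextureSeries:
    """Per-frame ASM over a stack, relative to a pre-treatment frame.

    The quantization grid is fixed from the reference frame's intensity
    range (linear binning), so a network fading toward its spatial mean
    collapses into fewer levels and homogeneity rises — matching how
    texture softens when a structure dissolves. Per-frame adaptive binning
    would instead re-stretch the residual noise every frame.
    """
    ref = stack[reference_index]
    sel = mask if mask is not None else np.ones(ref.data.shape, bool)
    lo, hi = float(ref.data[sel].min()), float(ref.data[sel].max())
    asm = [glcm_asm(frame, n_levels=n_levels, mask=mask, binning="linear",
                    value_range=(lo, hi)) for frame in stack]
    if times is None:
        times = np.asarray(stack.times, dtype=float)
    return relative_homogeneity(asm, reference_index, times=times)


def relative_homogeneity(asm_values: Sequence[float], reference_index: int,
                         times: Sequence[float] | None = None) -> TextureSeries:
    """ASM series divided by its value at ``reference_index`` (the time point
    right before treatment); the reference maps to exactly 1."""
    asm = np.asarray(asm_values, dtype=float)
    if times is None:
        times = np.arange(len(asm), dtype=float)
    return TextureSeries(times=np.asarray(times, dtype=float), asm=asm,
                         reference_index=int(reference_index))
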