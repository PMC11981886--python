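"""Voxel-wise twitch landmark detection, metrics, parametric maps,
histograms and thresholded category maps.

For each conditioned voxel trace four landmarks are located: the onset of
signal change (first time the signal falls more than three baseline
standard deviations below the baseline mean), the first and second signal
minima, and the point closest to baseline between them.  The derived
metrics are

    rise time          = t_min1   - t_start
    contraction time   = t_middle - t_start
    half-relaxation    = t_min2   - t_min1

computed per voxel and summarised over the muscle mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .core import DynamicSeries, MuscleMask
from .preprocess import condition_trace

__all__ = [
    "BaselineStats",
    "TwitchLandmarks",
    "TwitchMetrics",
    "MetricMap",
    "HistogramSummary",
    "CategoryMap",
    "DetectionConfig",
    "estimate_baseline",
    "detect_landmarks",
    "compute_metrics",
    "map_metrics",
    "build_histogram",
    "threshold_map",
    "FIXED_CATEGORY_EDGES",
]

METRIC_NAMES = ("t_rise", "t_contract", "t_half_relax")

#: Fixed contraction-time category edges (ms) used by the thresholded maps.
FIXED_CATEGORY_EDGES = (100.0, 150.0, 200.0)


@dataclass
class BaselineStats:
    mean: float
    sd: float
    n: int


@dataclass
class TwitchLandmarks:
    """Per-voxel landmark times in ms, with a validity flag."""

    t_start: Optional[float] = None
    t_min1: Optional[float] = None
    t_middle: Optional[float] = None
    t_min2: Optional[float] = None
    valid: bool = False
    failure_reason: Optional[str] = None  # no_onset | lt_two_minima | order_violation

    def as_tuple(self):
        return (self.t_start, self.t_min1, self.t_middle, self.t_min2)


@dataclass
class TwitchMetrics:
    t_rise: Optional[float] = None
    t_contract: Optional[float] = None
    t_half_relax: Optional[float] = None
    valid: bool = False
    failure_reason: Optional[str] = None


@dataclass
class DetectionConfig:
    """Tunables of conditioning and landmark detection."""

    smoothing_window: int = 3  # frames
    target_step: float = 0.5  # ms
    onset_multiplier: float = 3.0  # onset when signal < mean - mult*SD
    prominence_multiplier: float = 3.0  # minimum prominence in baseline SDs
    min_minimum_separation: float = 10.0  # ms between the two minima
    fallback_window: float = 400.0  # ms after onset searched by the fallback
    min_baseline_samples: int = 5
    refine_minima: bool = True  # parabolic sub-sample refinement of minima
    refine_halfwidth_min1: float = 10.0  # ms fit window around the sharp first dip
    refine_halfwidth_min2: float = 20.0  # ms fit window around the flatter second dip


def estimate_baseline(
    times, values, min_samples: int = 5
) -> BaselineStats:
    """Mean and SD of the unstimulated baseline (samples at negative
    time-since-stimulus)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    base = values[times < 0]
    if len(base) < min_samples:
        raise ValueError(
            f"only {len(base)} baseline samples at negative latency; "
            f"need at least {min_samples}"
        )
    # sample SD (ddof=1): the baseline is a sample used to estimate noise
    return BaselineStats(float(base.mean()), float(base.std(ddof=1)), len(base))


def detect_landmarks(
    times,
    values,
    baseline: BaselineStats,
    config: DetectionConfig | None = None,
) -> TwitchLandmarks:
    """Locate the four twitch landmarks on a conditioned trace.

    Onset is the first post-stimulus sample below ``mean - mult*SD``.  The
    two signal minima are the two most prominent local minima after onset
    passing a prominence criterion of ``prominence_multiplier * SD`` (the
    twitch dips dwarf noise dips, so ranking by prominence is robust to
    spurious shallow minima); when exactly one prominent minimum is found,
    the second is recovered as the global minimum of the remaining
    post-onset window.  Minimum locations are refined sub-sample by a
    least-squares parabola over a window matched to each dip's width.  The
    middle landmark is the sample between the minima closest to the
    baseline mean (ties to the earlier time).
    """
    cfg = config or DetectionConfig()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if baseline.sd < 0:
        raise ValueError("baseline SD must be >= 0")

    threshold = baseline.mean - cfg.onset_multiplier * baseline.sd
    post = times >= 0
    onset_candidates = np.flatnonzero(post & (values < threshold))
    if onset_candidates.size == 0:
        return TwitchLandmarks(valid=False, failure_reason="no_onset")
    i_start = int(onset_candidates[0])
    t_start = float(times[i_start])

    seg = values[i_start:]
    seg_t = times[i_start:]
    prominence = max(cfg.prominence_multiplier * baseline.sd, 1e-12)
    found, props = find_peaks(-seg, prominence=prominence)
    if len(found) > 2:
        found = found[np.argsort(props["prominences"])[-2:]]
    minima_idx = sorted(int(i) for i in found)

    if len(minima_idx) == 1:
        # fallback: global minimum of the post-onset window away from the
        # detected minimum
        m1 = minima_idx[0]
        in_window = seg_t <= t_start + cfg.fallback_window
        apart = np.abs(seg_t - seg_t[m1]) >= cfg.min_minimum_separation
        cand = np.flatnonzero(in_window & apart)
        if cand.size:
            m2 = int(cand[np.argmin(seg[cand])])
            lo, hi = sorted((m1, m2))
            rebound = seg[lo : hi + 1].max() if hi > lo else -np.inf
            # only accept if the trace genuinely rises between the two dips
            if seg[m2] < baseline.mean and rebound >= max(seg[m1], seg[m2]) + prominence:
                minima_idx.append(m2)
    if len(minima_idx) < 2:
        return TwitchLandmarks(
            t_start=t_start, valid=False, failure_reason="lt_two_minima"
        )
    i1, i2 = sorted(minima_idx[:2])
    t_min1, t_min2 = float(seg_t[i1]), float(seg_t[i2])

    between = slice(i1 + 1, i2)
    if between.stop - between.start < 1:
        return TwitchLandmarks(
            t_start=t_start, t_min1=t_min1, t_min2=t_min2,
            valid=False, failure_reason="order_violation",
        )
    # closest to baseline mean; np.argmin resolves ties to the earlier time
    i_mid = between.start + int(np.argmin(np.abs(seg[between] - baseline.mean)))
    t_middle = float(seg_t[i_mid])

    if cfg.refine_minima:
        t_min1 = _parabolic_refine(seg_t, seg, i1, cfg.refine_halfwidth_min1)
        t_min2 = _parabolic_refine(seg_t, seg, i2, cfg.refine_halfwidth_min2)

    lm = TwitchLandmarks(t_start, t_min1, t_middle, t_min2)
    if t_start < t_min1 < t_middle < t_min2:
        lm.valid = True
    else:
        lm.failure_reason = "order_violation"
    return lm


def _parabolic_refine(times: np.ndarray, values: np.ndarray, i: int, half_width: float) -> float:
    """Sub-sample minimum location: vertex of a least-squares parabola
    fitted over ``half_width`` ms either side of the grid minimum at index
    ``i``.  The shift is clamped to the fit window; non-convex fits return
    the grid time unchanged."""
    t0 = float(times[i])
    sel = (times >= t0 - half_width) & (times <= t0 + half_width)
    coef = np.polyfit(times[sel] - t0, values[sel], 2)
    if coef[0] <= 0:
        return t0
    vertex = -coef[1] / (2.0 * coef[0])
    return t0 + float(np.clip(vertex, -half_width, half_width))


def compute_metrics(landmarks: TwitchLandmarks) -> TwitchMetrics:
    """Rise, contraction and half-relaxation times from valid landmarks."""
    if not landmarks.valid:
        return TwitchMetrics(valid=False, failure_reason=landmarks.failure_reason)
    return TwitchMetrics(
        t_rise=landmarks.t_min1 - landmarks.t_start,
        t_contract=landmarks.t_middle - landmarks.t_start,
        t_half_relax=landmarks.t_min2 - landmarks.t_min1,
        valid=True,
    )


@dataclass
class MetricMap:
    """Scalar parametric image (ms) over a muscle mask.

    Invalid or out-of-mask voxels carry NaN, never zero; summary
    statistics cover valid in-mask voxels only.
    """

    values: np.ndarray  # float grid, NaN where invalid/outside
    valid: np.ndarray  # bool grid
    name: str
    mean: float
    sd: float
    n_valid: int
    excluded_fraction: float

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def map_metrics(
    series: DynamicSeries,
    mask: MuscleMask,
    config: DetectionConfig | None = None,
) -> dict[str, MetricMap]:
    """Run conditioning, landmark detection and metric computation for
    every in-mask voxel, producing the three parametric maps."""
    cfg = config or DetectionConfig()
    series._check_congruent(mask)
    if series.time_unit != "ms":
        raise ValueError("metric mapping expects a latency (ms) series")
    n_mask = mask.n_voxels

    grids = {m: np.full(series.grid_shape, np.nan) for m in METRIC_NAMES}
    valid = np.zeros(series.grid_shape, dtype=bool)
    times = series.frame_times
    for r, c in mask.indices():
        trace = series.voxel_trace(r, c)
        fine_t, fine_v = condition_trace(
            times, trace, window=cfg.smoothing_window, target_step=cfg.target_step
        )
        base = estimate_baseline(fine_t, fine_v, min_samples=cfg.min_baseline_samples)
        metrics = compute_metrics(detect_landmarks(fine_t, fine_v, base, cfg))
        if metrics.valid:
            valid[r, c] = True
            grids["t_rise"][r, c] = metrics.t_rise
            grids["t_contract"][r, c] = metrics.t_contract
            grids["t_half_relax"][r, c] = metrics.t_half_relax

    n_valid = int(valid.sum())
    excluded = 1.0 - n_valid / n_mask
    if excluded > 0.5:
        warnings.warn(
            f"{excluded:.0%} of in-mask voxels failed landmark detection"
        )
    out = {}
    for m in METRIC_NAMES:
        vals = grids[m][valid]
        out[m] = MetricMap(
            values=grids[m],
            valid=valid.copy(),
            name=m,
            mean=float(vals.mean()) if n_valid else float("nan"),
            sd=float(vals.std(ddof=0)) if n_valid else float("nan"),
            n_valid=n_valid,
            excluded_fraction=excluded,
        )
    return out


@dataclass
class HistogramSummary:
    """50-bin histogram of valid voxel values with a Gaussian-kernel
    density estimate (Silverman bandwidth)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density_x: np.ndarray
    density_y: np.ndarray
    n_valid: int


def build_histogram(
    maps: MetricMap | Sequence[MetricMap],
    bins: int = 50,
    density_points: int = 512,
) -> HistogramSummary:
    """Histogram of one map or of several maps pooled over a shared range."""
    if isinstance(maps, MetricMap):
        maps = [maps]
    pooled = np.concatenate([m.valid_values() for m in maps]) if maps else np.array([])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no valid voxels to histogram")

    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:  # degenerate single-value map
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(pooled, bins=bins, range=(lo, hi))

    spread = pooled.std(ddof=0)
    if pooled.size > 1 and spread > 0:
        kde = gaussian_kde(pooled, bw_method="silverman")
        bw = float(np.sqrt(kde.covariance[0, 0]))
    else:
        bw = max(1e-3, (hi - lo) / 100.0)
        kde = None
    # extend the abscissa well past the data so the density integrates to 1
    x = np.linspace(lo - 6 * bw, hi + 6 * bw, density_points)
    if kde is not None:
        y = kde(x)
    else:
        mu = float(pooled.mean())
        y = np.exp(-0.5 * ((x - mu) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    return HistogramSummary(edges, counts, x, y, int(pooled.size))


@dataclass
class CategoryMap:
    """Four-class partition of a metric map.

    ``fixed_edges`` uses (min, e1], (e1, e2], (e2, e3], (e3, max];
    ``equal_span`` splits [min, max] into four equal intervals.  Classes
    are 1..4; invalid voxels carry 0.
    """

    classes: np.ndarray  # int grid, 0 where invalid/outside
    edges: tuple[float, float, float]
    mode: str


def threshold_map(
    metric_map: MetricMap,
    mode: str = "fixed_edges",
    edges: tuple[float, float, float] = FIXED_CATEGORY_EDGES,
) -> CategoryMap:
    """Partition a metric map's valid voxels into four classes."""
    vals = metric_map.valid_values()
    if vals.size == 0:
        raise ValueError("no valid voxels to categorise")
    lo, hi = float(vals.min()), float(vals.max())
    if mode == "equal_span":
        span = hi - lo
        edges = tuple(lo + span * q / 4.0 for q in (1, 2, 3))
    elif mode == "fixed_edges":
        edges = tuple(float(e) for e in edges)
        if not (edges[0] < edges[1] < edges[2]):
            raise ValueError("category edges must be strictly increasing")
        if edges[0] >= hi or edges[2] <= lo:
            warnings.warn(
                f"category edges {edges} lie largely outside the data range "
                f"[{lo:.1f}, {hi:.1f}]; some classes will be empty"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    classes = np.zeros(metric_map.values.shape, dtype=int)
    v = metric_map.values[metric_map.valid]
    # right-closed intervals: class = 1 + number of edges strictly below v
    cls = 1 + (v[:, None] > np.asarray(edges)[None, :]).sum(axis=1)
    classes[metric_map.valid] = cls
    return CategoryMap(classes, edges, mode)
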