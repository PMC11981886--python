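"""Cyclic phase-contrast reduction and fatigue-recovery modelling.

The post-fatigue recovery experiment samples a short window around the
expected twitch peak-velocity latency cyclically (five latency offsets per
cycle).  The reduction keeps the highest in-mask speed from each cycle,
yielding one peak-velocity sample per cycle, and the resulting recovery
curve is fitted with a modified Gompertz model

    y(x) = a * exp(-b * exp(-c * x)) - d

from which the time-to-half-maximum of the recovery is derived in closed
form.  A small mono-exponential utility fits metabolite-recovery tables of
the form y(t) = y_end - amplitude * exp(-rate * t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import DynamicSeries, MuscleMask

__all__ = [
    "RecoveryCurve",
    "GompertzFit",
    "MonoExpFit",
    "gompertz",
    "phase_to_velocity",
    "find_peak_latency",
    "extract_cycle_peaks",
    "fit_gompertz",
    "half_max_time",
    "normalize_curve",
    "fit_monoexponential",
]


def gompertz(x, a: float, b: float, c: float, d: float):
    """Modified Gompertz recovery curve ``a*exp(-b*exp(-c*x)) - d``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> exact 0 limit below
        return a * np.exp(-b * np.exp(-c * x)) - d


def gompertz_shifted(x, a: float, b: float, c: float, d: float, x0: float):
    """Five-parameter variant with an explicit time shift ``x0``.

    Note ``x0`` is redundant with ``b`` (``b' = b*exp(c*x0)``); it is kept
    as an opt-in parametrisation only.
    """
    return gompertz(np.asarray(x, dtype=float) - x0, a, b, c, d)


@dataclass
class RecoveryCurve:
    """Ordered per-cycle peak-velocity samples over recovery time."""

    times: np.ndarray  # s, strictly increasing, one per complete cycle
    values: np.ndarray  # cm/s
    source_frames: np.ndarray  # index of the winning frame per cycle
    winning_offsets: np.ndarray  # latency offset (ms) of the winning frame
    normalization: str = "raw"  # "raw" | "end_normalized"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("recovery times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class GompertzFit:
    """Fitted modified-Gompertz parameters and diagnostics."""

    a: Optional[float]
    b: Optional[float]
    c: Optional[float]
    d: Optional[float]
    x0: Optional[float]
    t_half_max: Optional[float]
    adjusted_r2: Optional[float]
    n: int
    residual_sd: Optional[float]
    converged: bool
    message: str = ""

    def predict(self, x) -> np.ndarray:
        if not self.converged:
            raise ValueError("cannot predict from a non-converged fit")
        if self.x0 is not None:
            return gompertz_shifted(x, self.a, self.b, self.c, self.d, self.x0)
        return gompertz(x, self.a, self.b, self.c, self.d)


@dataclass
class MonoExpFit:
    """Mono-exponential recovery y(t) = y_end - amplitude*exp(-rate*t)."""

    rate: Optional[float]  # 1/s
    amplitude: Optional[float]
    y_end: Optional[float]
    half_time: Optional[float]  # ln(2)/rate
    recovering: bool
    n: int
    residual_sd: Optional[float] = None


def phase_to_velocity(frame: np.ndarray, venc: float) -> tuple[np.ndarray, bool]:
    """Convert a phase frame (radians) to velocity (cm/s).

    v = (phase / pi) * venc.  Returns the velocity frame and an aliasing
    flag raised when any |phase| exceeds pi (velocity wrap).
    """
    if venc is None or venc <= 0:
        raise ValueError("venc (cm/s) must be provided and > 0")
    frame = np.asarray(frame, dtype=float)
    aliased = bool(np.any(np.abs(frame) > np.pi))
    return frame / np.pi * venc, aliased


def find_peak_latency(series: DynamicSeries, mask: MuscleMask) -> float:
    """Latency (ms) maximising the mean in-mask speed of a latency scan.

    The discrete maximum is refined by a quadratic fit through the peak and
    its two neighbours.  Ties resolve to the earliest latency with a
    warning.
    """
    if series.n_frames < 10:
        raise ValueError("peak-latency search needs at least 10 frames")
    speeds = series.mean_in_mask(mask, absolute=True)
    if np.all(speeds == 0):
        raise ValueError("all-zero velocity series: no peak latency")
    peak_val = speeds.max()
    peaks = np.flatnonzero(speeds == peak_val)
    if len(peaks) > 1:
        warnings.warn("multiple equal velocity maxima; taking the earliest latency")
    i = int(peaks[0])
    t = series.frame_times
    if 0 < i < len(t) - 1:
        # quadratic sub-sample refinement on the three points around the peak
        y0, y1, y2 = speeds[i - 1], speeds[i], speeds[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            step = 0.5 * (t[i + 1] - t[i - 1])
            return float(t[i] + np.clip(delta, -1, 1) * step)
    return float(t[i])


def extract_cycle_peaks(
    series: DynamicSeries,
    mask: MuscleMask,
    cycle_length: int = 5,
    summary: str = "mean",
) -> RecoveryCurve:
    """Reduce a cyclic PC series to one peak-velocity sample per cycle.

    Each sample is the maximum over the cycle of the per-frame in-mask
    speed summary (mean by default, median selectable); its timestamp is
    the midpoint of the cycle's frame times.  An incomplete trailing cycle
    is dropped with a warning.
    """
    n = series.n_frames
    if cycle_length > n:
        raise ValueError(f"cycle_length {cycle_length} exceeds frame count {n}")
    n_cycles = n // cycle_length
    if n % cycle_length:
        warnings.warn(
            f"dropping incomplete trailing cycle of {n % cycle_length} frame(s)"
        )
    if summary == "mean":
        per_frame = series.mean_in_mask(mask, absolute=True)
    elif summary == "median":
        series._check_congruent(mask)
        per_frame = np.median(np.abs(series.data[mask.data, :]), axis=0)
    else:
        raise ValueError(f"unknown summary {summary!r}")

    offsets = None
    if series.sidecar is not None and "offset_ms" in series.sidecar:
        offsets = series.sidecar["offset_ms"].to_numpy(dtype=float)

    times = np.empty(n_cycles)
    values = np.empty(n_cycles)
    src = np.empty(n_cycles, dtype=int)
    won = np.full(n_cycles, np.nan)
    for j in range(n_cycles):
        sl = slice(j * cycle_length, (j + 1) * cycle_length)
        block = per_frame[sl]
        i_win = int(np.argmax(block))
        values[j] = block[i_win]
        times[j] = series.frame_times[sl].mean()
        src[j] = j * cycle_length + i_win
        if offsets is not None:
            won[j] = offsets[j * cycle_length + i_win]
    return RecoveryCurve(times, values, src, won)


def _adjusted_r2(y: np.ndarray, resid: np.ndarray, n_params: int) -> Optional[float]:
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0 or n - n_params - 1 <= 0:
        return None
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_gompertz(
    curve: RecoveryCurve,
    n_restarts: int = 5,
    seed: int = 0,
    with_time_shift: bool = False,
    half_max_definition: str = "plateau_half",
) -> GompertzFit:
    """Nonlinear least-squares fit of the modified Gompertz curve.

    Initialisation: a <- max(y), d <- max(0, -min(y)), c <- 2/x-range,
    b solved from the first sample; plus ``n_restarts`` jittered restarts
    drawn from a seeded generator.  The best-cost converged solution wins.
    """
    x, y = curve.times, curve.values
    n = len(x)
    n_params = 5 if with_time_shift else 4
    if n < 8:
        raise ValueError("Gompertz fit needs at least 8 samples")
    if np.std(y) == 0 or np.ptp(y) < 1e-12 * max(1.0, abs(float(y[0]))):
        return GompertzFit(
            None, None, None, None, None, None, None, n, None, False,
            message="constant curve: growth rate unidentifiable",
        )

    a0 = float(np.max(y))
    d0 = max(0.0, -float(np.min(y)))
    xr = float(np.ptp(x)) or 1.0
    c0 = 2.0 / xr
    ratio = np.clip((y[0] + d0) / max(a0, 1e-30), 1e-12, 1 - 1e-12)
    b0 = max(-np.log(ratio), 1e-6)

    def resid(theta):
        if with_time_shift:
            a, b, c, d, x0 = theta
            return gompertz_shifted(x, a, b, c, d, x0) - y
        a, b, c, d = theta
        return gompertz(x, a, b, c, d) - y

    lower = [1e-12, 1e-12, 1e-12, 0.0]
    upper = [np.inf] * 4
    theta0 = [a0, b0, c0, d0]
    if with_time_shift:
        lower += [-xr]
        upper += [xr]
        theta0 += [0.0]

    rng = np.random.default_rng(seed)
    starts = [np.asarray(theta0, dtype=float)]
    for _ in range(n_restarts):
        jitter = rng.lognormal(mean=0.0, sigma=0.5, size=4)
        s = np.asarray(theta0, dtype=float)
        s[:4] = np.maximum(s[:4] * jitter, 1e-10)
        starts.append(s)

    best = None
    for s in starts:
        try:
            sol = least_squares(
                resid, s, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=20000,
            )
        except Exception:  # pragma: no cover - solver blow-up
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return GompertzFit(
            None, None, None, None, None, None, None, n, None, False,
            message="no start converged",
        )

    if with_time_shift:
        a, b, c, d, x0 = (float(v) for v in best.x)
    else:
        a, b, c, d = (float(v) for v in best.x)
        x0 = None
    r = best.fun
    adj = _adjusted_r2(y, r, n_params)
    try:
        thm = half_max_time(a, b, c, d, definition=half_max_definition)
        if x0 is not None:
            thm += x0
    except ValueError:
        thm = None
    dof = max(n - n_params, 1)
    return GompertzFit(
        a, b, c, d, x0, thm, adj, n,
        residual_sd=float(np.sqrt(np.sum(r**2) / dof)),
        converged=True,
        message=best.message,
    )


def half_max_time(
    a: float, b: float, c: float, d: float = 0.0, definition: str = "plateau_half"
) -> float:
    """Closed-form time at which the Gompertz curve reaches half-recovery.

    ``plateau_half`` solves y(T) = (a-d)/2, half the asymptotic plateau:
    T = -(1/c) * ln( ln(2a/(a+d)) / b ).  ``range_half`` solves
    y(T) = (y(0)+y(inf))/2, the midpoint of the curve's own range.
    """
    if not (a > 0 and b > 0 and c > 0):
        raise ValueError("half-max time requires a > 0, b > 0, c > 0")
    if definition == "plateau_half":
        ratio = (a + d) / (2.0 * a)
        if not (0.0 < ratio < 1.0):
            raise ValueError(
                f"target level (a+d)/(2a) = {ratio:.4g} outside (0, 1); "
                "plateau half-level is not reached by this curve"
            )
        return float(-np.log(np.log(2.0 * a / (a + d)) / b) / c)
    if definition == "range_half":
        # midpoint of y(0)..y(inf); independent of a and d
        inner = -np.log((1.0 + np.exp(-b)) / 2.0) / b
        return float(-np.log(inner) / c)
    raise ValueError(f"unknown definition {definition!r}")


def normalize_curve(curve: RecoveryCurve, tail_fraction: float = 0.1) -> RecoveryCurve:
    """Divide the curve by the mean of its final ``tail_fraction`` samples."""
    n = curve.n_samples
    if n < 5:
        raise ValueError("normalization needs at least 5 samples")
    n_tail = max(1, int(np.ceil(tail_fraction * n)))
    end_mean = float(curve.values[-n_tail:].mean())
    if end_mean <= 0:
        raise ValueError(f"end-recovery mean {end_mean:.4g} is not positive")
    return replace(curve, values=curve.values / end_mean, normalization="end_normalized")


def fit_monoexponential(times, values) -> MonoExpFit:
    """Least-squares fit of y(t) = y_end - amplitude * exp(-rate * t).

    Flags the series as non-recovering when the fitted trend is not an
    upward exponential approach (amplitude or rate <= 0).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(t)
    if n < 6:
        raise ValueError("mono-exponential fit needs at least 6 samples")

    y_end0 = float(y[-1])
    amp0 = max(float(y[-1] - y[0]), 1e-12)
    k0 = 3.0 / (float(np.ptp(t)) or 1.0)

    def resid(theta):
        y_end, amp, k = theta
        return y_end - amp * np.exp(-k * t) - y

    sol = least_squares(
        resid, [y_end0, amp0, k0], xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000
    )
    y_end, amp, k = (float(v) for v in sol.x)
    recovering = amp > 0 and k > 0
    half = float(np.log(2.0) / k) if recovering else None
    dof = max(n - 3, 1)
    return MonoExpFit(
        rate=k if recovering else None,
        amplitude=amp,
        y_end=y_end,
        half_time=half,
        recovering=recovering,
        n=n,
        residual_sd=float(np.sqrt(np.sum(sol.fun**2) / dof)),
    )
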