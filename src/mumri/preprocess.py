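"""Registration, per-voxel trace conditioning and stimulation-current
selection — the steps upstream of landmark detection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import optical_flow_ilk, phase_cross_correlation
from skimage.transform import warp

from .core import DynamicSeries, MuscleMask

__all__ = [
    "CurrentRampResult",
    "register_series",
    "condition_trace",
    "select_stimulation_current",
]


@dataclass
class CurrentRampResult:
    """Outcome of the stimulation-current selection rule."""

    selected_current: Optional[float]  # mA; None when no crossing
    crossing_found: bool
    fraction: float  # target signal fraction of unstimulated baseline
    curve: pd.DataFrame  # columns: current_mA, signal_fraction


def _translate(frame: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    return ndimage.shift(frame, shift, order=3, mode="nearest")


def _windowed(frame: np.ndarray, window: np.ndarray) -> np.ndarray:
    # Hann apodisation suppresses the spectral leakage of non-periodic
    # image edges that otherwise biases phase correlation
    return (frame - frame.mean()) * window


def register_series(
    series: DynamicSeries,
    reference: int = 0,
    method: str = "translation",
    upsample_factor: int = 100,
    max_displacement: float = 10.0,
) -> tuple[DynamicSeries, pd.DataFrame]:
    """Align every frame to a reference frame.

    ``method="translation"`` estimates a per-frame subpixel shift by phase
    correlation; ``method="nonrigid"`` follows the translation with an
    iterative Lucas-Kanade optical-flow pass.  Frames whose estimated
    displacement magnitude exceeds ``max_displacement`` pixels are flagged
    as diverged and dropped from the returned series.

    Returns the registered series and a QC table with per-frame estimated
    displacement (dy, dx: how far the frame content had moved relative to
    the reference), displacement magnitude and an ``excluded`` flag.
    """
    if series.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    if method not in ("translation", "nonrigid"):
        raise ValueError(f"unknown registration method {method!r}")
    ref = series.frame(reference)
    hann = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    ref_w = _windowed(ref, hann)

    out = np.empty_like(series.data)
    rows = []
    for i in range(series.n_frames):
        frame = series.frame(i)
        if i == reference:
            out[:, :, i] = frame
            rows.append({"frame": i, "dy": 0.0, "dx": 0.0, "magnitude": 0.0, "excluded": False})
            continue
        correction, _, _ = phase_cross_correlation(
            ref_w, _windowed(frame, hann),
            upsample_factor=upsample_factor, normalization=None,
        )
        dy, dx = float(-correction[0]), float(-correction[1])
        mag = float(np.hypot(dy, dx))
        excluded = mag > max_displacement
        aligned = frame if excluded else _translate(frame, correction)
        if method == "nonrigid" and not excluded:
            flow = optical_flow_ilk(ref, aligned)
            nr, nc = ref.shape
            grid_r, grid_c = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
            aligned = warp(
                aligned,
                np.array([grid_r + flow[0], grid_c + flow[1]]),
                mode="edge",
                preserve_range=True,
            )
        out[:, :, i] = aligned
        rows.append({"frame": i, "dy": dy, "dx": dx, "magnitude": mag, "excluded": excluded})

    qc = pd.DataFrame(rows)
    if qc["excluded"].any():
        warnings.warn(
            f"{int(qc['excluded'].sum())} frame(s) exceeded the "
            f"{max_displacement} px displacement cap and were excluded"
        )
        keep = ~qc["excluded"].to_numpy()
        registered = series.with_data(out).subset_frames(keep)
    else:
        registered = series.with_data(out)
    return registered, qc


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with a shrinking window at the boundaries,
    so no samples are fabricated by padding."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    n = len(values)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def condition_trace(
    times,
    values,
    window: int = 3,
    target_step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth a voxel trace with a moving average, then resample it
    piecewise-linearly onto a uniform fine grid.

    The output grid spans the input latency range exactly with spacing
    ``target_step`` (ms, default 0.5).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values):
        raise ValueError("times and values differ in length")
    if not np.all(np.diff(times) > 0):
        raise ValueError("latency axis must be strictly increasing")
    if len(times) < 2 * window:
        raise ValueError(f"need at least {2 * window} frames for window {window}")
    smooth = moving_average(values, window)
    n_steps = int(round((times[-1] - times[0]) / target_step))
    fine = times[0] + target_step * np.arange(n_steps + 1)
    fine[-1] = times[-1]  # guard against float drift at the end of the span
    return fine, np.interp(fine, times, smooth)


def select_stimulation_current(
    ramp: DynamicSeries,
    mask: MuscleMask,
    fraction: float = 0.67,
    interpolate: bool = True,
) -> CurrentRampResult:
    """Select the stimulation current at which the mean in-mask signal
    first drops to ``fraction`` of the unstimulated baseline.

    The baseline is the first (zero/lowest-current) frame.  By default the
    crossing is linearly interpolated between the bracketing tested
    currents; with ``interpolate=False`` the first tested current at or
    below the target fraction is returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    currents = ramp.frame_times
    mean_signal = ramp.mean_in_mask(mask)
    baseline = mean_signal[0]
    if baseline <= 0:
        raise ValueError("non-positive baseline signal in mask")
    frac_curve = mean_signal / baseline
    curve = pd.DataFrame({"current_mA": currents, "signal_fraction": frac_curve})

    below = np.flatnonzero(frac_curve <= fraction)
    if below.size == 0:
        return CurrentRampResult(None, False, fraction, curve)
    j = int(below[0])
    if j == 0 or not interpolate:
        selected = float(currents[j])
    else:
        f0, f1 = frac_curve[j - 1], frac_curve[j]
        w = (fraction - f0) / (f1 - f0)
        selected = float(currents[j - 1] + w * (currents[j] - currents[j - 1]))
    return CurrentRampResult(selected, True, fraction, curve)
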