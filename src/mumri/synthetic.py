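"""Forward-model phantom generator with exact ground truth.

Generates the three acquisition types the analysis pipeline consumes:

* a stimulated latency series in which every muscle voxel shows the
  biphasic signal dip produced by twitch contraction/relaxation motion,
* a cyclic velocity series sampling a twitch peak whose amplitude recovers
  along a Gompertz time course after fatigue, and
* a current-ramp series with a known signal-drop response.

The twitch tension model is gamma-shaped,

    F(t) = A * ((t-t0)/tau)**k * exp(-(t-t0)/tau)   for t > t0, else 0,

whose fibre velocity v = dF/dt has two interior speed maxima at
``t0 + tau*(k -/+ sqrt(k))`` and a single zero crossing at the tension
peak ``t0 + k*tau``.  These closed forms are the oracle for all
landmark-recovery tests.  Signal attenuation is mono-exponential in speed:
``S = S0 * exp(-beta * |v|)``; frames with negative time-since-stimulus
carry pure baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .core import DynamicSeries, MuscleMask
from .pc_recovery import gompertz

__all__ = [
    "TwitchKineticsParams",
    "PhantomConfig",
    "TwitchSimResult",
    "default_latency_axis",
    "twitch_tension",
    "twitch_velocity",
    "analytic_landmarks",
    "simulate_twitch_kinetics",
    "simulate_pgse_latency_series",
    "simulate_pc_recovery_series",
    "simulate_current_ramp",
    "default_phantom_config",
    "control_like_kinetics",
]

REGION_LABELS = ("superficial", "deep", "aponeurosis")


def default_latency_axis() -> np.ndarray:
    """Default stimulus-to-readout latency axis in ms.

    The stimulus is gated from 400 ms before to 45 ms after the excitation
    pulse in 5 ms increments, i.e. time-since-stimulus at readout runs from
    -45 ms to +400 ms: 90 acquisitions.
    """
    return np.arange(-45.0, 400.0 + 2.5, 5.0)


@dataclass(frozen=True)
class TwitchKineticsParams:
    """Parameters of the gamma-shaped twitch forward model for one voxel.

    ``beta`` (s/cm-like attenuation coefficient in model units) scales how
    strongly fibre speed attenuates the stimulated signal; ``s0`` is the
    unstimulated baseline signal.
    """

    t0: float = 10.0  # onset delay, ms
    k: float = 2.0  # shape, dimensionless (>= 2 so two speed maxima exist)
    tau: float = 50.0  # timescale, ms
    amplitude: float = 1.0  # tension units
    beta: float = 0.0  # attenuation per unit speed
    s0: float = 100.0  # baseline signal

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.k < 2:
            raise ValueError("shape k must be >= 2")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.s0 <= 0:
            raise ValueError("baseline signal must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def peak_speed(self) -> float:
        """Maximum |dF/dt|, attained at t0 + tau*(k - sqrt(k))."""
        u = self.k - np.sqrt(self.k)
        return abs(
            self.amplitude / self.tau * u ** (self.k - 1) * np.exp(-u) * (self.k - u)
        )

    def with_dip_to(self, floor_fraction: float) -> "TwitchKineticsParams":
        """Copy with beta set so the deepest signal dip reaches
        ``floor_fraction * s0``."""
        if not 0 < floor_fraction < 1:
            raise ValueError("floor_fraction must be in (0, 1)")
        ps = self.peak_speed
        if ps == 0:
            raise ValueError("zero-amplitude twitch has no dip")
        return TwitchKineticsParams(
            self.t0, self.k, self.tau, self.amplitude,
            beta=-np.log(floor_fraction) / ps, s0=self.s0,
        )


def twitch_tension(t, p: TwitchKineticsParams) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    u = np.maximum((t - p.t0) / p.tau, 0.0)
    return p.amplitude * u**p.k * np.exp(-u)


def twitch_velocity(t, p: TwitchKineticsParams) -> np.ndarray:
    """dF/dt of the tension model (per ms)."""
    t = np.asarray(t, dtype=float)
    u = np.maximum((t - p.t0) / p.tau, 0.0)
    return p.amplitude / p.tau * u ** (p.k - 1) * np.exp(-u) * (p.k - u)


def analytic_landmarks(p: TwitchKineticsParams) -> dict[str, float]:
    """Closed-form landmark times (ms) of the twitch model.

    Onset at t0; speed maxima (signal minima) at t0 + tau*(k -/+ sqrt(k));
    tension peak / velocity zero (signal back at baseline) at t0 + k*tau.
    """
    rk = np.sqrt(p.k)
    lm = {
        "t_start": p.t0,
        "t_min1": p.t0 + p.tau * (p.k - rk),
        "t_middle": p.t0 + p.k * p.tau,
        "t_min2": p.t0 + p.tau * (p.k + rk),
    }
    lm["t_rise"] = lm["t_min1"] - lm["t_start"]
    lm["t_contract"] = lm["t_middle"] - lm["t_start"]
    lm["t_half_relax"] = lm["t_min2"] - lm["t_min1"]
    return lm


@dataclass
class TwitchSimResult:
    """Traces and analytic landmark times from one simulated twitch."""

    time: np.ndarray
    tension: np.ndarray
    velocity: np.ndarray
    landmarks: Optional[dict[str, float]]  # None when amplitude == 0


def simulate_twitch_kinetics(p: TwitchKineticsParams, time_axis) -> TwitchSimResult:
    """Sample the twitch tension/velocity model on a time axis.

    Raises when the axis stops before the second speed maximum, naming the
    span required to contain it.
    """
    t = np.asarray(time_axis, dtype=float)
    if p.amplitude == 0:
        return TwitchSimResult(t, np.zeros_like(t), np.zeros_like(t), None)
    t_min2 = p.t0 + p.tau * (p.k + np.sqrt(p.k))
    if t[-1] < t_min2 or t[0] > p.t0:
        raise ValueError(
            f"time axis [{t[0]:g}, {t[-1]:g}] ms too short: it must cover "
            f"[{p.t0:g}, {t_min2:g}] ms to contain the second speed maximum"
        )
    return TwitchSimResult(t, twitch_tension(t, p), twitch_velocity(t, p), analytic_landmarks(p))


@dataclass
class PhantomConfig:
    """Geometry, regional kinetics and noise of the latency-scan phantom.

    The muscle is an axis-aligned ellipse split into three concentric
    bands: a fast superficial rim, an intermediate deep band and a slow
    peri-aponeurosis core (normalised elliptical radius > 2/3, 1/3..2/3,
    <= 1/3 respectively).
    """

    grid_size: tuple[int, int] = (64, 64)
    muscle_center: tuple[float, float] = (31.5, 31.5)
    muscle_semiaxes: tuple[float, float] = (20.0, 14.0)
    regional_kinetics: Mapping[str, TwitchKineticsParams] = field(default_factory=dict)
    latency_axis: np.ndarray = field(default_factory=default_latency_axis)
    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    background_signal: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.latency_axis = np.asarray(self.latency_axis, dtype=float)
        if not np.all(np.diff(self.latency_axis) > 0):
            raise ValueError("latency axis must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not self.regional_kinetics:
            self.regional_kinetics = _default_regional_kinetics()
        missing = set(REGION_LABELS) - set(self.regional_kinetics)
        if missing:
            raise ValueError(f"regional_kinetics missing regions: {sorted(missing)}")


def _default_regional_kinetics() -> dict[str, TwitchKineticsParams]:
    # superficial fibres twitch fastest, the peri-aponeurosis core slowest;
    # beta tuned so every region dips to ~37% of baseline at peak speed
    return {
        "superficial": TwitchKineticsParams(t0=10.0, k=2.0, tau=35.0, s0=100.0).with_dip_to(np.exp(-1)),
        "deep": TwitchKineticsParams(t0=10.0, k=2.0, tau=50.0, s0=100.0).with_dip_to(np.exp(-1)),
        "aponeurosis": TwitchKineticsParams(t0=10.0, k=2.0, tau=65.0, s0=100.0).with_dip_to(np.exp(-1)),
    }


def control_like_kinetics() -> TwitchKineticsParams:
    """Kinetics tuned so the true rise time is ~39 ms and the true
    contraction time ~116 ms, matching the scale of healthy muscle."""
    k = 2.27
    tau = 116.0 / k
    return TwitchKineticsParams(t0=10.0, k=k, tau=tau, s0=100.0).with_dip_to(np.exp(-1))


def default_phantom_config(**overrides) -> PhantomConfig:
    return PhantomConfig(**overrides)


def _region_map(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (muscle mask, region label grid with '' outside)."""
    rows, cols = config.grid_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = config.muscle_center
    ar, ac = config.muscle_semiaxes
    rho = np.sqrt(((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2)
    mask = rho <= 1.0
    labels = np.full(config.grid_size, "", dtype=object)
    labels[mask & (rho > 2.0 / 3.0)] = "superficial"
    labels[mask & (rho > 1.0 / 3.0) & (rho <= 2.0 / 3.0)] = "deep"
    labels[mask & (rho <= 1.0 / 3.0)] = "aponeurosis"
    return mask, labels


def _add_noise(signal: np.ndarray, sd: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sd, signal.shape)
    # rician: magnitude of complex gaussian perturbation
    re = signal + rng.normal(0.0, sd, signal.shape)
    im = rng.normal(0.0, sd, signal.shape)
    return np.sqrt(re**2 + im**2)


def simulate_pgse_latency_series(
    config: PhantomConfig,
) -> tuple[DynamicSeries, MuscleMask, pd.DataFrame]:
    """Simulate a stimulated latency series over a leg-like cross-section.

    Returns the series, the muscle mask and a per-voxel ground-truth table
    (row, col, region, landmark times, derived metrics).
    """
    rng = np.random.default_rng(config.rng_seed)
    mask, labels = _region_map(config)
    rows, cols = config.grid_size
    axis = config.latency_axis
    data = np.full((rows, cols, len(axis)), config.background_signal, dtype=float)

    truth_rows = []
    for region in REGION_LABELS:
        p = config.regional_kinetics[region]
        sel = labels == region
        if not sel.any():
            continue
        speed = np.abs(twitch_velocity(axis, p))
        speed[axis < 0] = 0.0  # stimulus after readout: pure baseline
        trace = p.s0 * np.exp(-p.beta * speed)
        data[sel, :] = trace
        lm = analytic_landmarks(p)
        for r, c in np.argwhere(sel):
            truth_rows.append({"row": int(r), "col": int(c), "region": region, **lm})

    data = _add_noise(data, config.noise_sd, config.noise_model, rng)
    series = DynamicSeries(
        data,
        axis,
        time_unit="ms",
        modality="pgse_magnitude",
        sidecar=pd.DataFrame({"frame": np.arange(len(axis)), "time": axis}),
    )
    truth = pd.DataFrame(truth_rows).sort_values(["row", "col"]).reset_index(drop=True)
    return series, MuscleMask(mask, label="muscle"), truth


DEFAULT_CYCLE_OFFSETS = (-10.0, -5.0, 0.0, 5.0, 10.0)
LATENCY_KERNEL_FWHM_MS = 30.0


def latency_response_kernel(offset_ms, fwhm: float = LATENCY_KERNEL_FWHM_MS) -> np.ndarray:
    """Unimodal (Gaussian) twitch velocity profile vs latency offset,
    normalised to 1 at zero offset."""
    offset_ms = np.asarray(offset_ms, dtype=float)
    return np.exp(-4.0 * np.log(2.0) * offset_ms**2 / fwhm**2)


def simulate_pc_recovery_series(
    gompertz_truth: tuple[float, float, float, float],
    n_dynamics: int = 600,
    cycle_offsets=DEFAULT_CYCLE_OFFSETS,
    frame_period: float = 2.0,
    peak_latency_drift: float = 0.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    grid_size: tuple[int, int] = (16, 16),
) -> tuple[DynamicSeries, MuscleMask, pd.DataFrame]:
    """Simulate a cyclic post-fatigue velocity recovery series.

    Each frame's in-mask velocity is V(t) * g(offset - drift*t) + noise,
    where V is the Gompertz recovery curve ``gompertz_truth = (a, b, c, d)``
    (time in s), g the latency-response kernel and ``peak_latency_drift``
    a slow shift of the twitch peak latency in ms/s.  The truth table holds
    V evaluated at each cycle midpoint, plus a flag when the drifted peak
    leaves the sampled latency window.
    """
    a, b, c, d = gompertz_truth
    offsets = np.asarray(cycle_offsets, dtype=float)
    cycle_len = len(offsets)
    if n_dynamics <= 0:
        raise ValueError("n_dynamics must be positive")
    rng = np.random.default_rng(rng_seed)

    rows, cols = grid_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = ((rr - (rows - 1) / 2) / (rows * 0.35)) ** 2 + (
        (cc - (cols - 1) / 2) / (cols * 0.3)
    ) ** 2 <= 1.0

    idx = np.arange(n_dynamics)
    t = idx * frame_period
    frame_offsets = offsets[idx % cycle_len]
    cycles = idx // cycle_len
    drifted = frame_offsets - peak_latency_drift * t
    v_frame = gompertz(t, a, b, c, d) * latency_response_kernel(drifted)

    data = np.zeros((rows, cols, n_dynamics))
    data[mask, :] = v_frame
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)

    series = DynamicSeries(
        data,
        t,
        time_unit="s",
        modality="pc_velocity",
        sidecar=pd.DataFrame(
            {
                "frame": idx,
                "time": t,
                "cycle": cycles,
                "offset_ms": frame_offsets,
            }
        ),
    )

    n_cycles = n_dynamics // cycle_len
    mids = np.array([t[j * cycle_len : (j + 1) * cycle_len].mean() for j in range(n_cycles)])
    max_off = np.abs(offsets).max()
    peak_outside = np.array(
        [abs(peak_latency_drift) * tm > max_off for tm in mids], dtype=bool
    )
    truth = pd.DataFrame(
        {
            "cycle": np.arange(n_cycles),
            "time": mids,
            "v_true": gompertz(mids, a, b, c, d),
            "peak_outside_window": peak_outside,
        }
    )
    return series, MuscleMask(mask, label="muscle"), truth


def sigmoid_drop_response(
    i50: float = 13.0, width: float = 1.5, floor: float = 0.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Non-increasing signal-fraction-vs-current response for ramp phantoms."""

    def response(current):
        current = np.asarray(current, dtype=float)
        return floor + (1.0 - floor) / (1.0 + np.exp((current - i50) / width))

    return response


def simulate_current_ramp(
    currents,
    response: Callable[[np.ndarray], np.ndarray] | None = None,
    grid_size: tuple[int, int] = (32, 32),
    s0: float = 100.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    crossing_fraction: float = 0.67,
) -> tuple[DynamicSeries, MuscleMask, dict]:
    """Simulate a stimulation-current ramp series.

    The truth dict records the current at which the response first crosses
    ``crossing_fraction`` of baseline, located independently of the
    analysis path by dense-grid linear interpolation; ``None`` with a
    ``crossing_found=False`` flag when the response floor stays above it.
    """
    currents = np.asarray(currents, dtype=float)
    if currents.size == 0:
        raise ValueError("currents list is empty")
    if not np.all(np.diff(currents) > 0):
        raise ValueError("currents must be strictly increasing")
    if response is None:
        response = sigmoid_drop_response()
    rng = np.random.default_rng(rng_seed)

    rows, cols = grid_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = ((rr - (rows - 1) / 2) / (rows * 0.35)) ** 2 + (
        (cc - (cols - 1) / 2) / (cols * 0.3)
    ) ** 2 <= 1.0

    frac = np.asarray(response(currents), dtype=float)
    data = np.full((rows, cols, len(currents)), 0.3 * s0)
    data[mask, :] = s0 * frac
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)

    # dense-grid truth crossing (independent of the analysis interpolation)
    dense = np.linspace(currents[0], currents[-1], 20001)
    dense_frac = np.asarray(response(dense), dtype=float)
    below = np.flatnonzero(dense_frac <= crossing_fraction)
    if below.size:
        j = below[0]
        if j == 0:
            true_crossing = float(dense[0])
        else:
            f0, f1 = dense_frac[j - 1], dense_frac[j]
            w = (crossing_fraction - f0) / (f1 - f0)
            true_crossing = float(dense[j - 1] + w * (dense[j] - dense[j - 1]))
        truth = {"crossing_found": True, "true_crossing_mA": true_crossing}
    else:
        truth = {"crossing_found": False, "true_crossing_mA": None}

    series = DynamicSeries(
        data,
        currents,
        time_unit="mA",
        modality="pgse_magnitude",
        sidecar=pd.DataFrame({"frame": np.arange(len(currents)), "time": currents}),
    )
    return series, MuscleMask(mask, label="muscle"), truth
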