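"""Core data containers shared by every pipeline stage.

A :class:`DynamicSeries` is a 2D pixel grid acquired repeatedly along an
ordered frame axis.  The frame axis may carry stimulus-to-readout latencies
(milliseconds, for twitch-profile scans), wall-clock times (seconds, for
cyclic recovery scans) or stimulation currents (milliamperes, for ramp
scans).  All internal latency times follow the convention "time since
stimulus at slice readout": frames whose stimulus fires after the readout
have negative time and constitute the unstimulated baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["DynamicSeries", "MuscleMask", "FrameUnit", "Modality"]

#: Allowed frame-axis units.
FrameUnit = ("ms", "s", "mA")

#: Allowed modalities.
Modality = ("pgse_magnitude", "pc_velocity", "pc_phase")


@dataclass
class DynamicSeries:
    """A 2D+frame image series.

    Parameters
    ----------
    data:
        Array of shape ``(rows, cols, n_frames)``.
    frame_times:
        One value per frame: stimulus latency (ms), wall-clock time (s) or
        current (mA), matching ``time_unit``.
    time_unit:
        One of ``"ms"``, ``"s"``, ``"mA"``.
    modality:
        ``"pgse_magnitude"``, ``"pc_velocity"`` or ``"pc_phase"``.
    venc:
        Velocity encoding in cm/s; required iff modality is ``pc_phase``.
    pixel_spacing:
        In-plane pixel spacing in mm.
    sidecar:
        Optional per-frame table (cycle index, latency offset, ...).
    """

    data: np.ndarray
    frame_times: np.ndarray
    time_unit: str = "ms"
    modality: str = "pgse_magnitude"
    venc: Optional[float] = None
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    sidecar: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (rows, cols, frames), got shape {self.data.shape}")
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.data.shape[2]:
            raise ValueError(
                f"frame axis length {len(self.frame_times)} does not match "
                f"number of frames {self.data.shape[2]}"
            )
        if self.time_unit not in FrameUnit:
            raise ValueError(f"unknown time_unit {self.time_unit!r}")
        if self.modality not in Modality:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "pc_phase" and (self.venc is None or self.venc <= 0):
            raise ValueError("venc (cm/s) is required and must be > 0 for pc_phase data")
        if self.time_unit == "ms" and len(self.frame_times) > 1:
            if not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("latency axis must be strictly increasing")
        if self.sidecar is not None and len(self.sidecar) != self.n_frames:
            raise ValueError(
                f"sidecar has {len(self.sidecar)} rows but series has {self.n_frames} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def frame(self, i: int) -> np.ndarray:
        return self.data[:, :, i]

    def voxel_trace(self, row: int, col: int) -> np.ndarray:
        """Signal of one voxel along the frame axis."""
        return self.data[row, col, :]

    def mean_in_mask(self, mask: "MuscleMask", absolute: bool = False) -> np.ndarray:
        """Per-frame mean of in-mask values (optionally of absolute values)."""
        self._check_congruent(mask)
        vals = self.data[mask.data, :]
        if absolute:
            vals = np.abs(vals)
        return vals.mean(axis=0)

    def with_data(self, data: np.ndarray) -> "DynamicSeries":
        return replace(self, data=data)

    def subset_frames(self, keep: np.ndarray) -> "DynamicSeries":
        """Series restricted to the frames selected by boolean/index array."""
        keep = np.asarray(keep)
        sidecar = None if self.sidecar is None else self.sidecar.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep].reset_index(drop=True)
        return replace(
            self,
            data=self.data[:, :, keep],
            frame_times=self.frame_times[keep],
            sidecar=sidecar,
        )

    def _check_congruent(self, mask: "MuscleMask") -> None:
        if mask.data.shape != self.grid_shape:
            raise ValueError(
                f"mask shape {mask.data.shape} does not match series grid {self.grid_shape}"
            )


@dataclass
class MuscleMask:
    """Binary region of interest congruent with a series' pixel grid."""

    data: np.ndarray
    label: str = "muscle"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.data.any():
            raise ValueError("mask contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 2) array of in-mask (row, col) indices."""
        return np.argwhere(self.data)
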