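"""Time-stamped 3D landmark trajectories.

The common currency of the pipeline: a single marker's position sampled at
a constant interval (default 3 min), in millimetres, with optional
onset/offset annotations delimiting the movement window and optional
per-frame reprojection residuals carried over from triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["Trajectory3D", "DEFAULT_DT_MIN", "SAMPLING_FREQUENCY_HZ"]

#: Inter-frame interval used throughout the study design, minutes.
DEFAULT_DT_MIN = 3.0


def SAMPLING_FREQUENCY_HZ(dt_min: float = DEFAULT_DT_MIN, ndigits: int = 4) -> float:
    """Acquisition frequency in Hz for a frame interval of ``dt_min`` minutes.

    A 3-minute interval corresponds to 1/180 s ≈ 0.0056 Hz.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    return round(1.0 / (dt_min * 60.0), ndigits)


@dataclass
class Trajectory3D:
    """Ordered 3D samples (mm) of one landmark at constant time spacing (min)."""

    times: np.ndarray
    positions: np.ndarray
    marker_id: str = "tendril"
    onset: int | None = None
    offset: int | None = None
    residuals: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.times.shape != (self.positions.shape[0],):
            raise ValueError("times and positions lengths differ")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must be equally spaced")
        if self.residuals is not None:
            self.residuals = np.asarray(self.residuals, dtype=float)
            if self.residuals.shape != self.times.shape:
                raise ValueError("residuals must align with times")
            if np.any(self.residuals < 0):
                raise ValueError("residuals must be non-negative")
        if self.onset is not None and self.offset is not None:
            if not (0 <= self.onset <= self.offset < len(self.times)):
                raise ValueError("onset/offset out of range or inverted")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Sampling interval in minutes."""
        if len(self.times) < 2:
            raise ValueError("dt undefined for fewer than 2 samples")
        return float(self.times[1] - self.times[0])

    def slice(self, start: int, stop: int) -> "Trajectory3D":
        """Sub-trajectory over frame indices [start, stop] inclusive."""
        if not (0 <= start < stop < len(self.times)):
            raise ValueError(f"invalid slice [{start}, {stop}] for n={len(self.times)}")
        return replace(
            self,
            times=self.times[start : stop + 1],
            positions=self.positions[start : stop + 1],
            residuals=None if self.residuals is None else self.residuals[start : stop + 1],
            onset=None,
            offset=None,
            meta=dict(self.meta),
        )
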