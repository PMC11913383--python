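"""Circumnutation-cycle segmentation and kinematic dependent variables.

From one 3D tendril trajectory, restricted to its movement window (onset =
first frame of tendril development, offset = first frame of wrapping or
the frame before a fall), this module computes the six per-observation
metrics used in the condition comparisons:

(i)   movement time (min),
(ii)  average velocity during circumnutation (mm/min),
(iii) time of the peak velocity as % of movement time,
(iv)  mean duration of a circumnutation cycle (min),
(v)   total number of complete cycles,
(vi)  mean cycle length (mm) — the maximum pairwise distance between two
      sampled points within a cycle.

A cycle is operationally defined here as one full 2π accumulation of the
unwrapped polar angle of the detrended trajectory projected on the plane
orthogonal to the growth axis; a trailing partial revolution is reported
but not counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory3D

__all__ = [
    "CycleSegmentation",
    "KinematicRecord",
    "movement_window",
    "velocity_profile",
    "average_velocity",
    "peak_velocity_time",
    "segment_cycles",
    "cycle_length",
    "summarize",
    "records_to_frame",
    "auto_detect_window",
    "RECORD_COLUMNS",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "plant_id",
    "condition",
    "movement_time_min",
    "avg_velocity_mm_min",
    "peak_velocity_time_pct",
    "cycle_duration_min",
    "n_cycles",
    "cycle_length_mm",
    "outcome",
]


@dataclass
class Cycle:
    start: int  # frame index, inclusive
    end: int  # frame index, inclusive
    duration_min: float
    length_mm: float


@dataclass
class CycleSegmentation:
    """Contiguous, non-overlapping circumnutation cycles of one trajectory."""

    cycles: list[Cycle]
    growth_axis: np.ndarray
    partial_fraction: float  # trailing incomplete revolution, in turns
    period_estimate_min: float | None

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def mean_duration_min(self) -> float:
        return float(np.mean([c.duration_min for c in self.cycles])) if self.cycles else np.nan

    @property
    def mean_length_mm(self) -> float:
        return float(np.mean([c.length_mm for c in self.cycles])) if self.cycles else np.nan


@dataclass
class KinematicRecord:
    """One observation row: a plant × condition with its six metrics."""

    plant_id: str
    condition: str
    movement_time_min: float
    avg_velocity_mm_min: float
    peak_velocity_time_pct: float
    cycle_duration_min: float
    n_cycles: int
    cycle_length_mm: float
    outcome: str

    def __post_init__(self) -> None:
        if self.condition not in {"US", "LS", "IS", "DS"}:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.movement_time_min <= 0:
            raise ValueError("movement_time must be positive")
        if not 0.0 <= self.peak_velocity_time_pct <= 100.0:
            raise ValueError("peak_velocity_time_pct must lie in [0, 100]")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")


def movement_window(traj: Trajectory3D, onset: int, offset: int) -> Trajectory3D:
    """Restrict a trajectory to frames [onset, offset] inclusive.

    Movement time is (offset − onset) × dt minutes.
    """
    if onset >= offset:
        raise ValueError(f"onset ({onset}) must precede offset ({offset})")
    if onset < 0 or offset >= len(traj):
        raise ValueError(f"window [{onset}, {offset}] outside trajectory of {len(traj)} frames")
    return traj.slice(onset, offset)


def movement_time(traj: Trajectory3D, onset: int, offset: int) -> float:
    if onset >= offset:
        raise ValueError("onset must precede offset")
    return (offset - onset) * traj.dt


def velocity_profile(traj: Trajectory3D) -> np.ndarray:
    """Per-interval speed, mm/min, by forward finite difference on raw
    (unsmoothed) positions; speed_i covers the interval [t_i, t_{i+1})."""
    if len(traj) < 2:
        raise ValueError("velocity profile needs at least 2 samples")
    return np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) / traj.dt


def average_velocity(traj: Trajectory3D) -> float:
    """Mean speed over the whole (windowed) trajectory, mm/min."""
    return float(np.mean(velocity_profile(traj)))


def peak_velocity_time(traj: Trajectory3D) -> float:
    """Time of maximum speed as % of movement time; ties → first occurrence."""
    speeds = velocity_profile(traj)
    i_peak = int(np.argmax(speeds))  # argmax takes the first maximum
    span = traj.times[-1] - traj.times[0]
    return float(100.0 * (traj.times[i_peak] - traj.times[0]) / span)


def _estimate_growth_axis(times: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Growth axis for detrending.

    The direction of net elongation: the linear time-trend of position when
    drift dominates the oscillation, otherwise the smallest-variance
    principal axis (the normal of the oscillation plane), falling back to
    vertical for degenerate inputs.
    """
    t = times - times.mean()
    denom = float(t @ t)
    if denom == 0:
        return np.array([0.0, 0.0, 1.0])
    slope = (positions - positions.mean(axis=0)).T @ t / denom  # mm/min
    trend_span = np.linalg.norm(slope) * (times[-1] - times[0])
    detrended = positions - positions.mean(axis=0) - np.outer(t, slope)
    spread = float(np.sqrt(np.mean(np.sum(detrended**2, axis=1))))
    if trend_span > 2.0 * spread and trend_span > 1e-9:
        return slope / np.linalg.norm(slope)
    cov = np.cov(detrended.T)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0.0):
        return np.array([0.0, 0.0, 1.0])
    w, v = np.linalg.eigh(cov)
    axis = v[:, 0]  # smallest variance
    if w[1] < 1e-12:  # no oscillation plane to speak of
        return np.array([0.0, 0.0, 1.0])
    return axis / np.linalg.norm(axis)


def _dominant_period(planar: np.ndarray, dt: float) -> float | None:
    """Coarse period estimate (min) from the dominant spectral peak of the
    projected coordinates; None when no clear peak exists."""
    n = len(planar)
    if n < 8:
        return None
    centered = planar - planar.mean(axis=0)
    power = np.zeros(n // 2 + 1)
    for j in range(planar.shape[1]):
        power += np.abs(np.fft.rfft(centered[:, j])) ** 2
    power[0] = 0.0
    k = int(np.argmax(power))
    if k == 0:
        return None
    others = np.delete(power[1:], k - 1)
    if len(others) and power[k] < 5.0 * np.median(others):
        return None
    return n * dt / k


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; where the full window does not fit (the
    edges) the trend is extended linearly from the adjacent interior, which
    keeps pure oscillations exactly centred near the endpoints."""
    n = len(x)
    s = pd.Series(x)
    trend = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    half = window // 2
    lo, hi = half, n - 1 - half
    if hi - lo < 1:
        return trend
    for edge, interior in ((slice(0, lo), slice(lo, min(lo + window, hi + 1))),
                           (slice(hi + 1, n), slice(max(lo, hi + 1 - window), hi + 1))):
        idx = np.arange(n)[interior]
        if len(idx) >= 2:
            coef = np.polyfit(idx, trend[interior], 1)
            trend[edge] = np.polyval(coef, np.arange(n)[edge])
    return trend


def segment_cycles(traj: Trajectory3D, planar_lengths: bool = False) -> CycleSegmentation:
    """Segment a trajectory into circumnutation cycles.

    Procedure: (1) estimate the growth axis; (2) project positions onto the
    orthogonal plane; (3) subtract a centred moving-average trend whose
    window is one coarse period estimated from the dominant spectral peak
    (fallback 10 frames, logged); (4) unwrap the polar angle of the
    detrended planar signal; (5) every 2π of accumulated angle closes one
    cycle. The trailing partial revolution is reported as a fraction of a
    turn but excluded from the count. Cycle length is the maximum pairwise
    distance among the cycle's points (3D by default).
    """
    axis = _estimate_growth_axis(traj.times, traj.positions)
    if len(traj) < 4:
        logger.warning("segment_cycles: fewer than 4 samples, returning 0 cycles")
        return CycleSegmentation([], axis, 0.0, None)

    # orthonormal basis of the plane orthogonal to the growth axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    planar = traj.positions @ np.column_stack([e1, e2])

    dt = traj.dt
    period = _dominant_period(planar, dt)
    if period is None:
        window = 10
        logger.info("segment_cycles: no dominant spectral peak; fallback window 10 frames")
    else:
        window = max(3, int(round(period / dt)))
    if window % 2 == 0:
        window += 1
    trend = np.column_stack([_moving_average(planar[:, j], window) for j in range(2)])
    detrended = planar - trend

    r = np.linalg.norm(detrended, axis=1)
    ok = r > 1e-12
    if ok.sum() < 4:
        return CycleSegmentation([], axis, 0.0, period)
    angle = np.unwrap(np.arctan2(detrended[:, 1], detrended[:, 0]))
    total = angle[-1] - angle[0]
    sign = 1.0 if total >= 0 else -1.0
    cum = sign * (angle - angle[0])
    cum = np.maximum.accumulate(cum)  # monotone envelope against noise jitter

    two_pi = 2.0 * np.pi
    tol = 1e-6
    k_max = int(np.floor((cum[-1] + tol) / two_pi))
    bounds = [0]
    for k in range(1, k_max + 1):
        idx = int(np.searchsorted(cum, k * two_pi - tol))
        idx = min(idx, len(cum) - 1)
        if idx <= bounds[-1]:
            continue
        bounds.append(idx)

    pts = planar if planar_lengths else traj.positions
    cycles = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        cycles.append(
            Cycle(
                start=s,
                end=e,
                duration_min=(e - s) * dt,
                length_mm=cycle_length(pts[s : e + 1]),
            )
        )
    partial = float((cum[-1] - (len(bounds) - 1) * two_pi) / two_pi)
    if partial > 1e-9:
        logger.info("segment_cycles: trailing partial cycle of %.2f turns discarded", partial)
    return CycleSegmentation(cycles, axis, max(partial, 0.0), period)


def cycle_length(points: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance among sampled points, mm.

    Exact O(n²); cycles hold few samples at 3-min sampling.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("cycle length needs at least 2 points")
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def auto_detect_window(traj: Trajectory3D, frac: float = 0.05, run: int = 3) -> tuple[int, int]:
    """Heuristic onset/offset for synthetic data: the first/last frame of a
    run of ``run`` consecutive intervals with speed above ``frac`` of the
    maximum. Real recordings use visually annotated windows instead."""
    speeds = velocity_profile(traj)
    thr = frac * speeds.max()
    above = speeds > thr
    onset, offset = None, None
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= run:
            onset = i - run + 1
            break
    count = 0
    for i in range(len(above) - 1, -1, -1):
        count = count + 1 if above[i] else 0
        if count >= run:
            offset = i + run - 1 + 1  # last interval's right endpoint frame
            break
    if onset is None or offset is None or onset >= offset:
        raise ValueError("no movement window detected")
    return onset, min(offset, len(traj) - 1)


def summarize(
    traj: Trajectory3D,
    plant_id: str,
    condition: str,
    outcome: str,
    onset: int | None = None,
    offset: int | None = None,
) -> KinematicRecord:
    """Assemble the six metrics for one plant into a tidy record.

    Onset/offset default to the trajectory's annotations; they are required
    one way or the other (in the original protocol they were defined
    visually from the video).
    """
    onset = traj.onset if onset is None else onset
    offset = traj.offset if offset is None else offset
    if onset is None or offset is None:
        raise ValueError("onset/offset annotations are required")
    win = movement_window(traj, onset, offset)
    seg = segment_cycles(win)
    return KinematicRecord(
        plant_id=plant_id,
        condition=condition,
        movement_time_min=movement_time(traj, onset, offset),
        avg_velocity_mm_min=average_velocity(win),
        peak_velocity_time_pct=peak_velocity_time(win),
        cycle_duration_min=seg.mean_duration_min,
        n_cycles=seg.n_cycles,
        cycle_length_mm=seg.mean_length_mm,
        outcome=outcome,
    )


def records_to_frame(records: list[KinematicRecord]) -> pd.DataFrame:
    """Tidy DataFrame with the pipeline's canonical column names."""
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)
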