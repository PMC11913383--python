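"""Synthetic tendril trajectories and experiments with known ground truth.

Climbing-plant organs circumnutate: they sweep an oscillatory, roughly
elliptical path around a growth axis while elongating. This module
generates such trajectories (sampled every 3 minutes by default, matching
the study design), renders them through a calibrated two-camera rig into
2D pixel tracks, and simulates whole multi-plant experiments at the
kinematic-record level with programmed condition effects and plant-level
random intercepts — so every downstream stage (triangulation, cycle
segmentation, mixed models) can be tested against programmed truth without
any external data.

Condition codes follow the support-availability design: US (undivided
support), LS (lifted, aboveground only), IS (in-ground, roots only),
DS (double, split support on opposite sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .stereo import CameraModel, MarkerTrack2D
from .trajectory import DEFAULT_DT_MIN, Trajectory3D

__all__ = [
    "CircumnutationParams",
    "ConditionPreset",
    "ExperimentDesign",
    "METRICS",
    "CONDITIONS",
    "simulate_trajectory",
    "simulate_experiment",
    "simulate_study",
    "render_stereo",
    "default_presets",
    "default_design",
    "default_stereo_rig",
]

#: Tidy-record metric column names, fixed across the pipeline.
METRICS = (
    "movement_time_min",
    "avg_velocity_mm_min",
    "peak_velocity_time_pct",
    "cycle_duration_min",
    "n_cycles",
    "cycle_length_mm",
)

CONDITIONS = ("US", "LS", "IS", "DS")


@dataclass(frozen=True)
class CircumnutationParams:
    """Generative parameters for one circumnutating trajectory.

    The oscillation is an ellipse (semi-axes ``amplitude_major`` /
    ``amplitude_minor``, mm) in the plane orthogonal to a fixed vertical
    growth axis, completed once per ``period`` minutes, superimposed on
    linear growth (``growth_rate`` mm/min along the axis) and optional
    drift toward a support (``drift_rate`` mm/min; 0 = no support
    perceived). ``fall_time`` truncates the trajectory and appends a rapid
    downward segment, emulating a plant that fails to clasp and falls.
    """

    period: float
    amplitude_major: float
    amplitude_minor: float
    growth_rate: float = 0.0
    drift_rate: float = 0.0
    phase0: float = 0.0
    noise_sd: float = 0.0
    n_cycles: int = 5
    dt: float = DEFAULT_DT_MIN
    fall_time: float | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.amplitude_major < 0 or self.amplitude_minor < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fall_time is not None and self.fall_time <= 0:
            raise ValueError("fall_time must be positive when given")


@dataclass(frozen=True)
class ConditionPreset:
    """One support condition: trajectory parameters + clasp probability."""

    condition: str
    params: CircumnutationParams
    clasp_probability: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.clasp_probability <= 1.0:
            raise ValueError("clasp_probability must lie in [0, 1]")


def default_presets() -> list[ConditionPreset]:
    """Condition presets encoding the observed ordering of conditions.

    Amplitudes/periods are chosen so that tendrils under the undivided
    support (US) move faster and finish sooner than under the lifted
    support (LS), with the in-ground (IS) and double (DS) conditions
    intermediate — the sign structure of the study's contrasts. Clasp
    probabilities are the observed outcome fractions (13/13 US, 3/13 LS,
    0/13 IS, 8/13 DS).
    """
    return [
        ConditionPreset(
            "US",
            CircumnutationParams(
                period=80.0,
                amplitude_major=30.0,
                amplitude_minor=20.0,
                growth_rate=0.30,
                drift_rate=0.10,
                noise_sd=0.8,
                n_cycles=14,
            ),
            clasp_probability=13 / 13,
        ),
        ConditionPreset(
            "LS",
            CircumnutationParams(
                period=150.0,
                amplitude_major=25.0,
                amplitude_minor=15.0,
                growth_rate=0.20,
                drift_rate=0.0,
                noise_sd=0.8,
                n_cycles=14,
            ),
            clasp_probability=3 / 13,
        ),
        ConditionPreset(
            "IS",
            CircumnutationParams(
                period=140.0,
                amplitude_major=28.0,
                amplitude_minor=18.0,
                growth_rate=0.20,
                drift_rate=0.03,
                noise_sd=0.8,
                n_cycles=15,
            ),
            clasp_probability=0 / 13,
        ),
        ConditionPreset(
            "DS",
            CircumnutationParams(
                period=110.0,
                amplitude_major=26.0,
                amplitude_minor=17.0,
                growth_rate=0.25,
                drift_rate=0.06,
                noise_sd=0.8,
                n_cycles=18,
            ),
            clasp_probability=8 / 13,
        ),
    ]


@dataclass(frozen=True)
class ExperimentDesign:
    """Record-level experiment generator settings.

    ``fixed_effects[metric][condition]`` are additive shifts on top of
    ``baselines[metric]``; each plant draws one random intercept per metric
    (``random_intercept_sd``), each observation adds residual noise
    (``residual_sd``). The observational unit of the original study (the
    number of tracked landmarks per plant) is not fixed by the design, so
    ``observations_per_plant`` is a free parameter.
    """

    n_plants_per_condition: int
    baselines: dict[str, float]
    fixed_effects: dict[str, dict[str, float]]
    random_intercept_sd: dict[str, float]
    residual_sd: dict[str, float]
    observations_per_plant: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants_per_condition < 2:
            raise ValueError("need at least 2 plants per condition")
        if self.observations_per_plant < 1:
            raise ValueError("need at least 1 observation per plant")
        for d in (self.random_intercept_sd, self.residual_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")


def default_design(n_plants_per_condition: int = 13, seed: int = 0) -> ExperimentDesign:
    """Design whose programmed shifts mirror the sign structure (and the
    rough magnitude) of the study's condition contrasts, LS as baseline."""
    fe = {
        "avg_velocity_mm_min": {"US": 1.95, "LS": 0.0, "IS": 0.17, "DS": 0.99},
        "movement_time_min": {"US": -1059.6, "LS": 0.0, "IS": -110.3, "DS": -151.4},
        "peak_velocity_time_pct": {"US": 10.8, "LS": 0.0, "IS": 21.7, "DS": 2.7},
        "cycle_duration_min": {"US": -800.0, "LS": 0.0, "IS": -179.0, "DS": -322.0},
        "n_cycles": {"US": -6.52, "LS": 0.0, "IS": -2.12, "DS": -3.89},
        "cycle_length_mm": {"US": 22.3, "LS": 0.0, "IS": -5.8, "DS": 24.0},
    }
    baselines = {
        "avg_velocity_mm_min": 1.2,
        "movement_time_min": 2300.0,
        "peak_velocity_time_pct": 40.0,
        "cycle_duration_min": 1100.0,
        "n_cycles": 12.0,
        "cycle_length_mm": 110.0,
    }
    intercept_sd = {
        "avg_velocity_mm_min": 0.25,
        "movement_time_min": 200.0,
        "peak_velocity_time_pct": 12.0,
        "cycle_duration_min": 250.0,
        "n_cycles": 2.5,
        "cycle_length_mm": 10.0,
    }
    residual_sd = {
        "avg_velocity_mm_min": 0.75,
        "movement_time_min": 620.0,
        "peak_velocity_time_pct": 15.0,
        "cycle_duration_min": 500.0,
        "n_cycles": 6.0,
        "cycle_length_mm": 22.0,
    }
    return ExperimentDesign(
        n_plants_per_condition=n_plants_per_condition,
        baselines=baselines,
        fixed_effects=fe,
        random_intercept_sd=intercept_sd,
        residual_sd=residual_sd,
        seed=seed,
    )


def _plant_rng(seed: int, condition: str, plant_index: int) -> np.random.Generator:
    """One pseudo-random stream per plant, so adding plants never perturbs
    existing ones."""
    return np.random.default_rng([seed, CONDITIONS.index(condition), plant_index])


def simulate_trajectory(
    params: CircumnutationParams,
    target: np.ndarray | None = None,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> Trajectory3D:
    """Generate one circumnutating trajectory with attached ground truth.

    position(t) = start + growth·t·ẑ + drift(t) + ellipse(2πt/period + φ₀)
    + isotropic Gaussian noise, sampled at t = 0, dt, 2·dt, …,
    n_cycles·period. Drift moves toward ``target`` at ``drift_rate`` mm/min
    (capped at the target). ``meta`` records the programmed cycle
    boundaries, cycle count and noise-free mean (chord) speed.
    """
    start = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    rng = np.random.default_rng(seed)
    n = int(round(params.n_cycles * params.period / params.dt)) + 1
    if n < 1:
        raise ValueError("parameters yield an empty trajectory")
    t = np.arange(n) * params.dt

    omega = 2.0 * np.pi / params.period
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    clean = (
        start
        + np.outer(params.growth_rate * t, ez)
        + np.outer(params.amplitude_major * np.cos(omega * t + params.phase0), e1)
        + np.outer(params.amplitude_minor * np.sin(omega * t + params.phase0), e2)
    )
    if target is not None and params.drift_rate > 0:
        target = np.asarray(target, dtype=float)
        to_target = target - start
        dist = np.linalg.norm(to_target)
        if dist > 0:
            direction = to_target / dist
            travel = np.minimum(params.drift_rate * t, dist)
            clean = clean + np.outer(travel, direction)

    fell = params.fall_time is not None and params.fall_time < t[-1]
    if fell:
        keep = t <= params.fall_time
        t, clean = t[keep], clean[keep]

    speeds = np.linalg.norm(np.diff(clean, axis=0), axis=1) / params.dt
    true_mean_speed = float(np.mean(speeds)) if len(speeds) else 0.0
    frames_per_cycle = params.period / params.dt
    bounds = [
        int(round(k * frames_per_cycle))
        for k in range(params.n_cycles + 1)
        if round(k * frames_per_cycle) <= len(t) - 1
    ]

    positions = clean + rng.normal(0.0, params.noise_sd, clean.shape)
    offset = len(t) - 1
    if fell:
        # rapid drop over three frames after losing contact
        drops = np.array([50.0, 150.0, 300.0])
        fall_pts = positions[-1] + np.outer(drops, np.array([0.0, 0.0, -1.0]))
        fall_t = t[-1] + params.dt * np.arange(1, 4)
        t = np.concatenate([t, fall_t])
        positions = np.vstack([positions, fall_pts])

    return Trajectory3D(
        times=t,
        positions=positions,
        onset=0,
        offset=offset,
        meta={
            "params": params,
            "true_cycle_bounds": bounds,
            "true_n_cycles": len(bounds) - 1,
            "true_mean_speed": true_mean_speed,
            "fell": bool(fell),
            "seed": seed,
        },
    )


def simulate_experiment(
    design: ExperimentDesign, presets: list[ConditionPreset]
) -> tuple["pandas.DataFrame", dict]:  # noqa: F821
    """Simulate tidy kinematic records with programmed effects.

    Returns ``(records, ground_truth)``: one row per observation with
    columns plant_id, condition, the six metrics and outcome, plus the
    programmed fixed effects and variance components for recovery tests.
    """
    import pandas as pd

    if len(presets) < 2:
        raise ValueError("need at least 2 conditions")
    rows = []
    for preset in presets:
        c = preset.condition
        for p in range(design.n_plants_per_condition):
            rng = _plant_rng(design.seed, c, p)
            intercepts = {m: rng.normal(0.0, design.random_intercept_sd[m]) for m in METRICS}
            outcome = "clasped" if rng.random() < preset.clasp_probability else "fell"
            for _ in range(design.observations_per_plant):
                row = {"plant_id": f"{c}{p + 1:02d}", "condition": c, "outcome": outcome}
                for m in METRICS:
                    row[m] = (
                        design.baselines[m]
                        + design.fixed_effects[m].get(c, 0.0)
                        + intercepts[m]
                        + rng.normal(0.0, design.residual_sd[m])
                    )
                rows.append(row)
    records = pd.DataFrame(rows)
    truth = {
        "fixed_effects": design.fixed_effects,
        "random_intercept_sd": design.random_intercept_sd,
        "residual_sd": design.residual_sd,
        "baselines": design.baselines,
    }
    return records, truth


def simulate_study(
    presets: list[ConditionPreset] | None = None,
    n_plants_per_condition: int = 13,
    seed: int = 0,
) -> list[dict]:
    """Trajectory-level experiment: one simulated plant per row.

    Each plant gets its preset's parameters jittered by plant-level
    lognormal factors (≈10% sd on amplitudes/rates, ≈8% on the period — the
    trajectory-level analogue of a random intercept), a plant-specific
    phase, and an outcome drawn from the preset's clasp probability; plants
    that fail to clasp fall near the end of their run. Returns dicts with
    keys plant_id, condition, outcome, trajectory.
    """
    presets = default_presets() if presets is None else presets
    support = np.array([120.0, 0.0, 300.0])  # support 12 cm away, mm
    study = []
    for preset in presets:
        for p in range(n_plants_per_condition):
            rng = _plant_rng(seed, preset.condition, p)
            clasped = rng.random() < preset.clasp_probability
            base = preset.params
            jitter = rng.lognormal(0.0, [0.1, 0.1, 0.08, 0.1])
            period = base.period * jitter[2]
            params = replace(
                base,
                amplitude_major=base.amplitude_major * jitter[0],
                amplitude_minor=base.amplitude_minor * jitter[1],
                period=period,
                growth_rate=base.growth_rate * jitter[3],
                phase0=float(rng.uniform(0.0, 2.0 * np.pi)),
                fall_time=None
                if clasped
                else float(base.n_cycles * period * rng.uniform(0.6, 0.95)),
            )
            traj = simulate_trajectory(
                params,
                target=support if params.drift_rate > 0 else None,
                seed=int(rng.integers(2**31)),
            )
            traj.marker_id = "tendril"
            study.append(
                {
                    "plant_id": f"{preset.condition}{p + 1:02d}",
                    "condition": preset.condition,
                    "outcome": "clasped" if clasped else "fell",
                    "trajectory": traj,
                }
            )
    return study


def render_stereo(
    traj: Trajectory3D,
    cam_a: CameraModel,
    cam_b: CameraModel,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[MarkerTrack2D, MarkerTrack2D]:
    """Project a 3D trajectory into two calibrated cameras.

    Returns one 2D track per camera, frame index = time / dt. Points at or
    behind a camera are flagged missing for that camera. With
    ``pixel_noise_sd`` 0 the stereo triangulation inverts this map.
    """
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    frames = np.round(traj.times / traj.dt).astype(int)
    tracks = []
    for cam in (cam_a, cam_b):
        uv, valid = cam.project(traj.positions)
        if pixel_noise_sd > 0:
            uv = uv + rng.normal(0.0, pixel_noise_sd, uv.shape)
        tracks.append(
            MarkerTrack2D(
                marker_id=traj.marker_id, frames=frames, uv=uv, missing=~valid
            )
        )
    return tracks[0], tracks[1]


def _look_at(center: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation of a camera at ``center`` looking at ``target``
    (world z up, image y pointing down)."""
    f = target - center
    f = f / np.linalg.norm(f)
    x = np.cross(f, np.array([0.0, 0.0, 1.0]))
    x = x / np.linalg.norm(x)
    y = np.cross(f, x)  # completes right-handed (x, y, z=f) with y downward
    R = np.vstack([x, y, f])
    if np.linalg.det(R) < 0:
        R = np.vstack([x, -y, f])
    t = -R @ center
    return R, t


def default_stereo_rig(
    baseline_mm: float = 450.0,
    distance_mm: float = 1100.0,
    height_mm: float = 400.0,
    fx: float = 1400.0,
    image_size: tuple[int, int] = (1920, 1080),
) -> tuple[CameraModel, CameraModel]:
    """Two converging full-HD cameras 45 cm apart, ~1.1 m from the plant."""
    target = np.array([0.0, 0.0, 200.0])
    cams = []
    for sx in (-0.5, 0.5):
        center = np.array([sx * baseline_mm, -distance_mm, height_mm])
        R, t = _look_at(center, target)
        cams.append(
            CameraModel(
                fx=fx,
                fy=fx,
                cx=image_size[0] / 2.0,
                cy=image_size[1] / 2.0,
                rotation=R,
                translation=t,
                k1=-0.05,
                k2=0.01,
                p1=1e-4,
                p2=-1e-4,
            )
        )
    return cams[0], cams[1]
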