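"""Camera model, undistortion and two-view triangulation.

Reconstructs 3D landmark trajectories from per-camera 2D marker tracks,
given calibrated pinhole cameras with Brown–Conrady lens distortion
(3 radial + 2 tangential coefficients). Pixel convention: origin at the
top-left, x rightwards, y downwards, pixel centres at integer coordinates.
World units are millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory3D

__all__ = [
    "CameraModel",
    "MarkerTrack2D",
    "DegenerateGeometryError",
    "undistort",
    "distort",
    "triangulate",
    "reprojection_report",
]

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Raised when the two-view geometry cannot support triangulation."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with Brown–Conrady distortion and rigid pose.

    The pose maps world to camera coordinates: ``x_cam = R @ x_world + t``,
    with ``t`` in mm. Focal lengths and principal point are in pixels;
    distortion coefficients are dimensionless.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal (within 1e-8)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.rotation.T @ self.translation

    def to_camera(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        return pts @ self.rotation.T + self.translation

    def project(self, points_world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points to pixels.

        Returns ``(uv, valid)``; points at or behind the camera plane are
        marked invalid and their pixels set to NaN.
        """
        pc = self.to_camera(points_world)
        z = pc[:, 2]
        valid = z > 1e-9
        uv = np.full((len(pc), 2), np.nan)
        if valid.any():
            x = pc[valid, 0] / z[valid]
            y = pc[valid, 1] / z[valid]
            xd, yd = distort(x, y, self)
            uv[valid, 0] = self.fx * xd + self.cx
            uv[valid, 1] = self.fy * yd + self.cy
        return uv, valid


@dataclass
class MarkerTrack2D:
    """One marker's 2D pixel track in a single camera."""

    marker_id: str
    frames: np.ndarray  # int frame indices, strictly increasing
    uv: np.ndarray  # (n, 2) pixels; NaN where missing
    missing: np.ndarray  # bool per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.uv = np.asarray(self.uv, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.uv.shape != (len(self.frames), 2) or self.missing.shape != (len(self.frames),):
            raise ValueError("inconsistent track shapes")


def distort(x: np.ndarray, y: np.ndarray, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Forward Brown–Conrady distortion on normalized image coordinates."""
    r2 = x * x + y * y
    radial = 1.0 + cam.k1 * r2 + cam.k2 * r2**2 + cam.k3 * r2**3
    xd = x * radial + 2.0 * cam.p1 * x * y + cam.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + cam.p1 * (r2 + 2.0 * y * y) + 2.0 * cam.p2 * x * y
    return xd, yd


def undistort(
    point: tuple[float, float] | np.ndarray,
    cam: CameraModel,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> np.ndarray:
    """Map a pixel to undistorted normalized image coordinates.

    Inverts the radial+tangential model by fixed-point iteration. With all
    distortion coefficients zero this reduces to
    ``((u - cx)/fx, (v - cy)/fy)``.
    """
    pt = np.asarray(point, dtype=float)
    if pt.shape != (2,) or not np.all(np.isfinite(pt)):
        raise ValueError(f"undistort requires a finite (u, v) pair, got {point!r}")
    xd = (pt[0] - cam.cx) / cam.fx
    yd = (pt[1] - cam.cy) / cam.fy
    if cam.k1 == cam.k2 == cam.k3 == cam.p1 == cam.p2 == 0.0:
        return np.array([xd, yd])
    x, y = xd, yd
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + cam.k1 * r2 + cam.k2 * r2**2 + cam.k3 * r2**3
        dx = 2.0 * cam.p1 * x * y + cam.p2 * (r2 + 2.0 * x * x)
        dy = cam.p1 * (r2 + 2.0 * y * y) + 2.0 * cam.p2 * x * y
        x_new = (xd - dx) / radial
        y_new = (yd - dy) / radial
        if abs(x_new - x) < tol and abs(y_new - y) < tol:
            return np.array([x_new, y_new])
        x, y = x_new, y_new
    raise RuntimeError(f"undistortion did not converge for pixel {tuple(pt)}")


def _triangulate_point(
    xa: np.ndarray, xb: np.ndarray, Pa: np.ndarray, Pb: np.ndarray
) -> tuple[np.ndarray, float]:
    """Homogeneous DLT on one pair of normalized observations.

    Returns the 3D point and a conditioning measure (ratio of the two
    smallest singular values of the design matrix; small = ill-posed).
    """
    A = np.vstack(
        [
            xa[0] * Pa[2] - Pa[0],
            xa[1] * Pa[2] - Pa[1],
            xb[0] * Pb[2] - Pb[0],
            xb[1] * Pb[2] - Pb[1],
        ]
    )
    _, s, vt = np.linalg.svd(A)
    X = vt[-1]
    cond = s[-1] / s[-2] if s[-2] > 0 else np.inf
    if abs(X[3]) < 1e-14:
        return np.full(3, np.nan), cond
    return X[:3] / X[3], s[-2] / s[0]


def _refine_point(
    X0: np.ndarray, obs: list[tuple[np.ndarray, CameraModel]], max_iter: int = 20
) -> np.ndarray:
    """Gauss–Newton refinement of a 3D point on pixel reprojection error."""
    X = X0.copy()
    for _ in range(max_iter):
        J_rows, r_rows = [], []
        for uv, cam in obs:
            pc = cam.to_camera(X[None, :])[0]
            if pc[2] <= 1e-9:
                return X
            proj, _ = cam.project(X[None, :])
            r_rows.append(proj[0] - uv)
            # numerical Jacobian, central differences
            J = np.zeros((2, 3))
            h = 1e-4
            for j in range(3):
                Xp, Xm = X.copy(), X.copy()
                Xp[j] += h
                Xm[j] -= h
                pp, _ = cam.project(Xp[None, :])
                pm, _ = cam.project(Xm[None, :])
                J[:, j] = (pp[0] - pm[0]) / (2 * h)
            J_rows.append(J)
        J = np.vstack(J_rows)
        r = np.concatenate(r_rows)
        try:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        X = X + step
        if np.linalg.norm(step) < 1e-12:
            break
    return X


def _reprojection_residual(X: np.ndarray, uv_a, uv_b, cam_a, cam_b) -> float:
    ra, _ = cam_a.project(X[None, :])
    rb, _ = cam_b.project(X[None, :])
    return 0.5 * (np.linalg.norm(ra[0] - uv_a) + np.linalg.norm(rb[0] - uv_b))


def triangulate(
    track_a: MarkerTrack2D,
    track_b: MarkerTrack2D,
    cam_a: CameraModel,
    cam_b: CameraModel,
    dt: float = 3.0,
    refine: bool = False,
    min_ray_angle_rad: float = 1e-6,
) -> Trajectory3D:
    """Two-view triangulation of shared frames into a 3D trajectory.

    Frames missing in either camera are dropped (and logged), not
    interpolated. Per-frame linear DLT on undistorted rays; optional
    Gauss–Newton reprojection refinement. Time is frame index × ``dt`` min.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    baseline = np.linalg.norm(cam_a.center - cam_b.center)
    if baseline < 1e-9:
        raise DegenerateGeometryError("cameras share a centre (zero baseline)")

    shared, ia, ib = np.intersect1d(track_a.frames, track_b.frames, return_indices=True)
    dropped = (len(track_a.frames) - len(shared)) + (len(track_b.frames) - len(shared))
    if dropped:
        logger.info("triangulate: dropped %d unshared frame entries", dropped)

    Pa = np.hstack([cam_a.rotation, cam_a.translation[:, None]])
    Pb = np.hstack([cam_b.rotation, cam_b.translation[:, None]])

    times, points, residuals = [], [], []
    n_flagged = 0
    for f, i, j in zip(shared, ia, ib):
        if track_a.missing[i] or track_b.missing[j]:
            n_flagged += 1
            continue
        uv_a, uv_b = track_a.uv[i], track_b.uv[j]
        if not (np.all(np.isfinite(uv_a)) and np.all(np.isfinite(uv_b))):
            n_flagged += 1
            continue
        xa = undistort(uv_a, cam_a)
        xb = undistort(uv_b, cam_b)
        # ray directions in world coordinates
        da = cam_a.rotation.T @ np.array([xa[0], xa[1], 1.0])
        db = cam_b.rotation.T @ np.array([xb[0], xb[1], 1.0])
        cos = abs(da @ db) / (np.linalg.norm(da) * np.linalg.norm(db))
        if np.arccos(np.clip(cos, 0.0, 1.0)) < min_ray_angle_rad:
            logger.info("triangulate: frame %d near-parallel rays, flagged missing", f)
            n_flagged += 1
            continue
        X, cond = _triangulate_point(xa, xb, Pa, Pb)
        if not np.all(np.isfinite(X)) or cond < 1e-12:
            logger.info("triangulate: frame %d ill-conditioned, flagged missing", f)
            n_flagged += 1
            continue
        if refine:
            X = _refine_point(X, [(uv_a, cam_a), (uv_b, cam_b)])
        times.append(f * dt)
        points.append(X)
        residuals.append(_reprojection_residual(X, uv_a, uv_b, cam_a, cam_b))

    if len(points) < 2:
        raise ValueError(
            f"triangulation needs >=2 usable shared frames, got {len(points)} "
            f"({n_flagged} flagged missing)"
        )
    frames_used = np.array([t / dt for t in times])
    if not np.allclose(np.diff(frames_used), np.diff(frames_used)[0]):
        # Trajectory3D requires constant spacing; keep the longest regular run.
        steps = np.diff(frames_used)
        common = np.bincount(steps.astype(int)).argmax()
        keep = [0]
        for idx in range(1, len(frames_used)):
            if frames_used[idx] - frames_used[keep[-1]] == common:
                keep.append(idx)
        logger.warning(
            "triangulate: irregular frame gaps; keeping %d/%d frames at spacing %d",
            len(keep),
            len(frames_used),
            int(common),
        )
        times = [times[i] for i in keep]
        points = [points[i] for i in keep]
        residuals = [residuals[i] for i in keep]

    return Trajectory3D(
        times=np.array(times),
        positions=np.array(points),
        marker_id=track_a.marker_id,
        residuals=np.array(residuals),
        meta={"n_flagged": n_flagged, "baseline_mm": float(baseline)},
    )


def reprojection_report(
    traj: Trajectory3D,
    tracks: tuple[MarkerTrack2D, MarkerTrack2D] | None = None,
    cams: tuple[CameraModel, CameraModel] | None = None,
) -> dict[str, float]:
    """Summary of per-frame reprojection residuals for a triangulated trajectory.

    If tracks and cameras are supplied, residuals are recomputed from scratch
    and checked against the values stored at triangulation time.
    """
    if len(traj) == 0 or traj.residuals is None:
        raise ValueError("trajectory carries no reprojection residuals")
    res = traj.residuals
    if tracks is not None and cams is not None:
        track_a, track_b = tracks
        cam_a, cam_b = cams
        frame_of = {int(f): i for i, f in enumerate(track_a.frames)}
        frame_of_b = {int(f): i for i, f in enumerate(track_b.frames)}
        recomputed = []
        for t, X in zip(traj.times, traj.positions):
            f = int(round(t / traj.dt))
            ia, ib = frame_of[f], frame_of_b[f]
            recomputed.append(
                _reprojection_residual(X, track_a.uv[ia], track_b.uv[ib], cam_a, cam_b)
            )
        if not np.allclose(recomputed, res, atol=1e-9):
            raise ValueError("stored residuals inconsistent with recomputation")
    return {
        "marker_id": traj.marker_id,
        "n_frames": len(res),
        "mean_residual_px": float(np.mean(res)),
        "max_residual_px": float(np.max(res)),
    }
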