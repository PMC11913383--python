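"""Plain-text readers and writers for the pipeline's tables.

All formats are comma-separated text with a ``#``-comment header carrying
the tool version and a hash of the generating configuration:

* trajectory tables: ``time_min,x_mm,y_mm,z_mm,marker_id``
* 2D track tables:   ``frame,marker_id,u,v,missing``
* calibration files: INI-style key-value text, one camera per section
* annotation tables: ``plant_id,marker_id,onset_frame,offset_frame,condition,outcome``
* tidy kinematic records and the two statistics tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .stereo import CameraModel, MarkerTrack2D
from .trajectory import Trajectory3D

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_tracks",
    "write_tracks",
    "read_calibration",
    "write_calibration",
    "read_records",
    "write_table",
    "read_annotations",
    "config_hash",
]

TRACK_COLUMNS = ["frame", "marker_id", "u", "v", "missing"]
TRAJ_COLUMNS = ["time_min", "x_mm", "y_mm", "z_mm", "marker_id"]
ANNOTATION_COLUMNS = [
    "plant_id",
    "marker_id",
    "onset_frame",
    "offset_frame",
    "condition",
    "outcome",
]


def config_hash(config: dict) -> str:
    """Stable sha256 of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header(config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# circumkin {__version__}\n# config_sha256={h}\n"


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # surface file name in parse failures
        raise ValueError(f"malformed table {path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: table has no data rows")
    for i, col in enumerate(required):
        if df[col].isna().all():
            raise ValueError(f"{path}: column {col!r} is entirely empty")
    return df


def write_table(df: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def write_trajectory(traj: Trajectory3D, path: str | Path, config: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_min": traj.times,
            "x_mm": traj.positions[:, 0],
            "y_mm": traj.positions[:, 1],
            "z_mm": traj.positions[:, 2],
            "marker_id": traj.marker_id,
        }
    )
    write_table(df, path, config)


def read_trajectory(path: str | Path, marker_id: str | None = None) -> Trajectory3D:
    df = _read_csv(path, TRAJ_COLUMNS)
    if marker_id is not None:
        df = df[df["marker_id"] == marker_id]
        if df.empty:
            raise ValueError(f"{path}: no rows for marker {marker_id!r}")
    mid = str(df["marker_id"].iloc[0])
    return Trajectory3D(
        times=df["time_min"].to_numpy(float),
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        marker_id=mid,
    )


def write_tracks(track: MarkerTrack2D, path: str | Path, config: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "frame": track.frames,
            "marker_id": track.marker_id,
            "u": track.uv[:, 0],
            "v": track.uv[:, 1],
            "missing": track.missing.astype(int),
        }
    )
    write_table(df, path, config)


def read_tracks(path: str | Path, marker_id: str | None = None) -> MarkerTrack2D:
    df = _read_csv(path, TRACK_COLUMNS)
    if marker_id is not None:
        df = df[df["marker_id"] == marker_id]
        if df.empty:
            raise ValueError(f"{path}: no rows for marker {marker_id!r}")
    mid = str(df["marker_id"].iloc[0])
    df = df[df["marker_id"] == mid]
    return MarkerTrack2D(
        marker_id=mid,
        frames=df["frame"].to_numpy(int),
        uv=df[["u", "v"]].to_numpy(float),
        missing=df["missing"].to_numpy(bool),
    )


_CAM_SCALARS = ["fx", "fy", "cx", "cy", "k1", "k2", "k3", "p1", "p2"]


def write_calibration(cams: dict[str, CameraModel], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# circumkin {__version__} calibration"]
    for name, cam in cams.items():
        lines.append(f"[{name}]")
        for key in _CAM_SCALARS:
            lines.append(f"{key} = {float(getattr(cam, key))!r}")
        lines.append("rotation = " + " ".join(repr(float(v)) for v in cam.rotation.ravel()))
        lines.append("translation = " + " ".join(repr(float(v)) for v in cam.translation))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_calibration(path: str | Path) -> dict[str, CameraModel]:
    """Parse an INI-style calibration file, one camera per section."""
    import configparser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calibration file not found: {path}")
    parser = configparser.ConfigParser(comment_prefixes=("#",))
    parser.read(path)
    cams: dict[str, CameraModel] = {}
    for section in parser.sections():
        raw = parser[section]
        try:
            kwargs = {k: float(raw.get(k, "0")) for k in _CAM_SCALARS}
            rotation = np.array([float(v) for v in raw["rotation"].split()]).reshape(3, 3)
            translation = np.array([float(v) for v in raw["translation"].split()])
        except (KeyError, ValueError) as err:
            raise ValueError(f"{path}: malformed camera section [{section}]: {err}") from err
        cams[section] = CameraModel(rotation=rotation, translation=translation, **kwargs)
    if not cams:
        raise ValueError(f"{path}: no camera sections found")
    return cams


def read_annotations(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ANNOTATION_COLUMNS)


def read_records(
    path: str | Path,
    column_mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tidy kinematic-record table.

    ``column_mapping`` maps external column names (e.g. from an archived
    per-observation deposit) onto the pipeline's canonical names
    ``{theirs: ours}``.
    """
    from .kinematics import RECORD_COLUMNS

    df = _read_csv(path, [])
    if column_mapping:
        df = df.rename(columns=column_mapping)
    required = ["plant_id", "condition"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    known = [c for c in RECORD_COLUMNS if c in df.columns]
    return df[known + [c for c in df.columns if c not in known]]
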