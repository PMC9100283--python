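"""Stream, calibration and configuration file formats.

Skeleton streams are CSV or JSONL with fields (frame_index, timestamp_s,
sensor_id, joint, x_mm, y_mm, z_mm, confidence); confidence serializes as
the literal strings ``medium``/``low``/``none``, and a ``none`` row carries
empty coordinates.  Calibration files are JSON, one record per sensor with
a row-major 9-float rotation and a 3-float translation in mm.  Fusion
configuration is YAML with ``fusion``/``kalman``/``dbscan`` sections; the
searching area accepts an explicit unit suffix (``10cm`` or ``100mm``).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FitDiagnostics, RigidTransform
from .core import JOINT_INDEX, JOINTS, Confidence, SkeletonTrack
from .fusion import FusionConfig, JointStatus, KalmanConfig, MergedTrack

__all__ = [
    "read_stream",
    "write_stream",
    "read_calibration",
    "write_calibration",
    "read_config",
    "parse_eps",
]

_STREAM_COLUMNS = ["frame_index", "timestamp_s", "sensor_id", "joint", "x_mm", "y_mm", "z_mm", "confidence"]
_STATUS_NAMES = {JointStatus.MISSING: "missing", JointStatus.PREDICTED: "predicted_only", JointStatus.MERGED: "merged"}


class SchemaError(ValueError):
    """A stream/config file violates the expected schema."""


def _track_to_rows(track: SkeletonTrack | MergedTrack, sensor_id: str | None = None) -> list[dict]:
    merged = isinstance(track, MergedTrack)
    if merged:
        sid = sensor_id or "merged"
        conf = np.where(track.status == JointStatus.MERGED, 2,
                        np.where(track.status == JointStatus.PREDICTED, 1, 0))
    else:
        sid = sensor_id or track.sensor_id
        conf = track.confidence
    ts = getattr(track, "timestamps_s", None)
    rows = []
    for i, fi in enumerate(track.frame_index):
        t = float(ts[i]) if ts is not None else float(fi) / 30.0
        for j, joint in enumerate(JOINTS):
            c = int(conf[i, j])
            p = track.positions[i, j]
            absent = c == 0 or not np.all(np.isfinite(p))
            row = {
                "frame_index": int(fi),
                "timestamp_s": t,
                "sensor_id": sid,
                "joint": joint,
                "x_mm": None if absent else float(p[0]),
                "y_mm": None if absent else float(p[1]),
                "z_mm": None if absent else float(p[2]),
                "confidence": str(Confidence(c if not absent else 0)),
            }
            if merged:
                row["status"] = _STATUS_NAMES[JointStatus(int(track.status[i, j]))]
                row["n_contributing"] = int(track.n_contributing[i, j])
            rows.append(row)
    return rows


def write_stream(track: SkeletonTrack | MergedTrack, path: str | Path,
                 sensor_id: str | None = None) -> None:
    """Write a stream as CSV or JSONL (chosen by file suffix)."""
    path = Path(path)
    rows = _track_to_rows(track, sensor_id)
    if path.suffix.lower() == ".jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
        return
    df = pd.DataFrame(rows)
    for c in ("x_mm", "y_mm", "z_mm"):
        df[c] = df[c].map(lambda v: "" if v is None else f"{v:.6f}")
    df["timestamp_s"] = df["timestamp_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def _rows_to_track(df: pd.DataFrame, path: Path) -> SkeletonTrack:
    missing = [c for c in _STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    sids = df["sensor_id"].unique()
    if len(sids) != 1:
        raise SchemaError(f"{path}: expected one sensor_id per stream file, found {list(sids)}")
    frame_ids = np.unique(df["frame_index"].to_numpy())
    lookup = {int(v): i for i, v in enumerate(frame_ids)}
    F, J = len(frame_ids), len(JOINTS)
    pos = np.full((F, J, 3), np.nan)
    conf = np.zeros((F, J), dtype=np.int8)
    ts = np.zeros(F)
    for r, row in enumerate(df.itertuples(index=False)):
        line = r + 2  # header is line 1
        joint = row.joint
        if joint not in JOINT_INDEX:
            raise SchemaError(f"{path}:{line}: unknown joint {joint!r}")
        try:
            c = Confidence.from_str(str(row.confidence))
        except ValueError as exc:
            raise SchemaError(f"{path}:{line}: {exc}") from None
        i = lookup[int(row.frame_index)]
        j = JOINT_INDEX[joint]
        ts[i] = float(row.timestamp_s)
        xyz = [row.x_mm, row.y_mm, row.z_mm]
        blank = [v is None or (isinstance(v, float) and math.isnan(v)) for v in xyz]
        if c == Confidence.NONE:
            conf[i, j] = 0
            continue
        if any(blank) or not all(math.isfinite(float(v)) for v in xyz):
            raise SchemaError(f"{path}:{line}: non-finite position with confidence {c}")
        pos[i, j] = [float(v) for v in xyz]
        conf[i, j] = int(c)
    return SkeletonTrack(str(sids[0]), frame_ids, pos, conf, timestamps_s=ts)


def read_stream(path: str | Path) -> SkeletonTrack:
    """Read a CSV or JSONL stream; schema violations name the offending line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".jsonl":
        records = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{ln}: invalid JSON ({exc})") from None
        df = pd.DataFrame(records)
        if df.empty:
            raise SchemaError(f"{path}: empty stream")
        for c in _STREAM_COLUMNS:
            if c not in df.columns:
                df[c] = None if c in ("x_mm", "y_mm", "z_mm") else np.nan
    else:
        df = pd.read_csv(path)
    return _rows_to_track(df, path)


def write_calibration(transforms: dict[str, tuple[RigidTransform, FitDiagnostics | None]],
                      path: str | Path) -> None:
    records = []
    for sid in sorted(transforms):
        t, diag = transforms[sid]
        rec = {
            "sensor_id": sid,
            "rotation": t.rotation.ravel().tolist(),
            "translation_mm": t.translation.tolist(),
        }
        if diag is not None:
            rec["diagnostics"] = {
                "rms_residual_mm": diag.rms_residual,
                "singular_values": diag.singular_values.tolist(),
                "reflection_corrected": diag.reflection_corrected,
            }
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def read_calibration(path: str | Path) -> dict[str, RigidTransform]:
    with open(path) as fh:
        records = json.load(fh)
    out = {}
    for rec in records:
        R = np.asarray(rec["rotation"], dtype=float).reshape(3, 3)
        t = np.asarray(rec["translation_mm"], dtype=float)
        out[rec["sensor_id"]] = RigidTransform(R, t)
    return out


def parse_eps(value) -> float:
    """Searching-area value -> mm; accepts numbers (mm) or '10cm'/'100mm' strings."""
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().lower()
    for suffix, factor in (("cm", 10.0), ("mm", 1.0), ("m", 1000.0)):
        if s.endswith(suffix):
            return float(s[: -len(suffix)]) * factor
    raise SchemaError(
        f"searching area {value!r} needs an explicit unit suffix (e.g. '10cm' or '100mm')"
    )


def read_config(path: str | Path) -> FusionConfig:
    """Load a :class:`FusionConfig` from YAML sections [fusion]/[kalman]/[dbscan]."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fusion = raw.get("fusion", {}) or {}
    kalman = raw.get("kalman", {}) or {}
    db = raw.get("dbscan", {}) or {}
    kwargs = {}
    if "variant" in fusion:
        kwargs["variant"] = str(fusion["variant"]).upper()
    if "use_reference_candidate" in fusion:
        kwargs["use_reference_candidate"] = bool(fusion["use_reference_candidate"])
    if "use_previous_candidate" in fusion:
        kwargs["use_previous_candidate"] = bool(fusion["use_previous_candidate"])
    if "max_coast_frames" in fusion:
        kwargs["max_coast_frames"] = int(fusion["max_coast_frames"])
    if "eps" in db:
        kwargs["eps_mm"] = parse_eps(db["eps"])
    elif "eps_mm" in db:
        kwargs["eps_mm"] = float(db["eps_mm"])
    if "min_neighbors" in db:
        kwargs["min_neighbors"] = int(db["min_neighbors"])
    kwargs["kalman"] = KalmanConfig(q=float(kalman.get("q", 0.01)), r=float(kalman.get("r", 1.0)))
    try:
        return FusionConfig(**kwargs)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None
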