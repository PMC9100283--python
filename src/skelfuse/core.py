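"""Skeleton topology shared by every stage of the fusion pipeline.

The tracked skeleton is the 16-joint subset of the Azure-Kinect-style body
model that is reliable under large motion: eight torso joints (pelvis,
spine_naval, neck, head, both shoulders, both hips), four upper-limb joints
(elbows, wrists) and four lower-limb joints (knees, ankles).  All positions
are millimeters in a right-handed frame; after marker calibration the z axis
points from floor to ceiling.

Each joint observation carries a tracker confidence with total order
``medium > low > none``: *medium* means tracked, *low* means estimated
(typically because the joint is occluded), *none* means outside the field of
view (no position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Confidence",
    "JointObservation",
    "SkeletonFrame",
    "SkeletonTrack",
    "JOINTS",
    "JOINT_INDEX",
    "REGIONS",
    "MIRROR_PAIRS",
    "BONES",
    "mirror_partner",
    "region_of",
    "joint_names",
    "frames_to_track",
    "track_to_frames",
]


class Confidence(IntEnum):
    """Tracker confidence level, ordered ``NONE < LOW < MEDIUM``."""

    NONE = 0
    LOW = 1
    MEDIUM = 2

    @classmethod
    def from_str(cls, s: str) -> "Confidence":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown confidence level {s!r}; expected medium/low/none") from None

    def __str__(self) -> str:  # serialized form
        return self.name.lower()


# (name, region, mirror partner or None); order fixes the array layout used
# throughout the package.
_JOINT_TABLE: tuple[tuple[str, str, str | None], ...] = (
    ("pelvis", "torso", None),
    ("spine_naval", "torso", None),
    ("neck", "torso", None),
    ("head", "torso", None),
    ("shoulder_L", "torso", "shoulder_R"),
    ("shoulder_R", "torso", "shoulder_L"),
    ("hip_L", "torso", "hip_R"),
    ("hip_R", "torso", "hip_L"),
    ("elbow_L", "upper_limb", "elbow_R"),
    ("elbow_R", "upper_limb", "elbow_L"),
    ("wrist_L", "upper_limb", "wrist_R"),
    ("wrist_R", "upper_limb", "wrist_L"),
    ("knee_L", "lower_limb", "knee_R"),
    ("knee_R", "lower_limb", "knee_L"),
    ("ankle_L", "lower_limb", "ankle_R"),
    ("ankle_R", "lower_limb", "ankle_L"),
)

#: optional 17th joint; off by default (the 16-joint set is canonical)
SPINE_CHEST = "spine_chest"

JOINTS: tuple[str, ...] = tuple(name for name, _, _ in _JOINT_TABLE)
JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINTS)}
REGIONS: dict[str, str] = {name: region for name, region, _ in _JOINT_TABLE}
_MIRROR: dict[str, str | None] = {name: partner for name, _, partner in _JOINT_TABLE}

#: index pairs (left, right) of mirrored joints, in array order
MIRROR_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (JOINT_INDEX[name], JOINT_INDEX[partner])
    for name, _, partner in _JOINT_TABLE
    if partner is not None and name.endswith("_L")
)

#: kinematic edges used for bone-length invariants (parent, child)
BONES: tuple[tuple[str, str], ...] = (
    ("pelvis", "spine_naval"),
    ("spine_naval", "neck"),
    ("neck", "head"),
    ("neck", "shoulder_L"),
    ("neck", "shoulder_R"),
    ("pelvis", "hip_L"),
    ("pelvis", "hip_R"),
    ("shoulder_L", "elbow_L"),
    ("shoulder_R", "elbow_R"),
    ("elbow_L", "wrist_L"),
    ("elbow_R", "wrist_R"),
    ("hip_L", "knee_L"),
    ("hip_R", "knee_R"),
    ("knee_L", "ankle_L"),
    ("knee_R", "ankle_R"),
)


def joint_names(include_chest: bool = False) -> tuple[str, ...]:
    """The tracked joint set; optionally extended with ``spine_chest``."""
    if include_chest:
        return JOINTS[:2] + (SPINE_CHEST,) + JOINTS[2:]
    return JOINTS


def _check_joint(j: str) -> None:
    if j not in JOINT_INDEX:
        raise ValueError(f"unknown joint name {j!r}")


def mirror_partner(j: str) -> str | None:
    """Contralateral joint for the 12 paired joints, ``None`` for midline joints."""
    _check_joint(j)
    return _MIRROR[j]


def region_of(j: str) -> str:
    """Body region of a joint: ``torso``, ``upper_limb`` or ``lower_limb``."""
    _check_joint(j)
    return REGIONS[j]


@dataclass(frozen=True)
class JointObservation:
    """One sensor's observation of one joint (position in mm)."""

    position: np.ndarray
    confidence: Confidence = Confidence.MEDIUM

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if self.confidence != Confidence.NONE and not np.all(np.isfinite(pos)):
            raise ValueError("non-finite position with confidence != none")


@dataclass
class SkeletonFrame:
    """One sensor's (possibly partial) 16-joint observation at one time step."""

    sensor_id: str
    frame_index: int
    joints: dict[str, JointObservation] = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        for j in self.joints:
            _check_joint(j)


@dataclass
class SkeletonTrack:
    """Dense array view of one sensor's stream.

    ``positions`` is (n_frames, 16, 3) in mm with NaN where the joint is
    absent; ``confidence`` is (n_frames, 16) of :class:`Confidence` codes.
    """

    sensor_id: str
    frame_index: np.ndarray
    positions: np.ndarray
    confidence: np.ndarray
    timestamps_s: np.ndarray | None = None

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=np.int8)
        f = len(self.frame_index)
        if self.positions.shape != (f, len(JOINTS), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({f}, {len(JOINTS)}, 3)"
            )
        if self.confidence.shape != (f, len(JOINTS)):
            raise ValueError("confidence shape mismatch")
        if f > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing within a stream")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def frame(self, i: int) -> SkeletonFrame:
        """The i-th frame as a :class:`SkeletonFrame` (positional index)."""
        joints = {}
        for j, name in enumerate(JOINTS):
            c = Confidence(int(self.confidence[i, j]))
            if c == Confidence.NONE:
                continue
            joints[name] = JointObservation(self.positions[i, j].copy(), c)
        return SkeletonFrame(self.sensor_id, int(self.frame_index[i]), joints)


def frames_to_track(frames: Iterable[SkeletonFrame], sensor_id: str | None = None) -> SkeletonTrack:
    """Pack per-frame observations into a dense :class:`SkeletonTrack`."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    sid = sensor_id if sensor_id is not None else frames[0].sensor_id
    idx = np.array([f.frame_index for f in frames], dtype=np.int64)
    pos = np.full((len(frames), len(JOINTS), 3), np.nan)
    conf = np.zeros((len(frames), len(JOINTS)), dtype=np.int8)
    for i, f in enumerate(frames):
        for name, obs in f.joints.items():
            j = JOINT_INDEX[name]
            conf[i, j] = int(obs.confidence)
            if obs.confidence != Confidence.NONE:
                pos[i, j] = obs.position
    return SkeletonTrack(sid, idx, pos, conf)


def track_to_frames(track: SkeletonTrack) -> list[SkeletonFrame]:
    return [track.frame(i) for i in range(track.n_frames)]


def stack_tracks(tracks: Mapping[str, SkeletonTrack]) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Align synchronized streams on the union of frame indices.

    Returns ``(sensor_ids, frame_index, positions, confidence)`` with
    ``positions`` shaped (n_sensors, n_frames, 16, 3); slots a sensor does
    not cover are confidence ``none``.
    """
    ids = sorted(tracks)
    if not ids:
        raise ValueError("no streams")
    all_idx = np.unique(np.concatenate([tracks[s].frame_index for s in ids]))
    S, F, J = len(ids), len(all_idx), len(JOINTS)
    pos = np.full((S, F, J, 3), np.nan)
    conf = np.zeros((S, F, J), dtype=np.int8)
    lookup = {int(v): i for i, v in enumerate(all_idx)}
    for si, s in enumerate(ids):
        t = tracks[s]
        rows = [lookup[int(v)] for v in t.frame_index]
        pos[si, rows] = t.positions
        conf[si, rows] = t.confidence
    return ids, all_idx, pos, conf
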