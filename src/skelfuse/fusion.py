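"""Merging per-sensor skeletons into a single tracked skeleton.

The merge runs three stages per synchronized time step:

1. *Arrangement* — per-sensor left/right label correction.  For every
   mirrored joint pair a cross-sensor reference position is formed (mean of
   medium-confidence candidates, falling back to low), and a sensor's pair is
   swapped when its "right" joint is closer to the reference of the wrong
   side than to its own.
2. *DBSCAN merging* — all sensor candidates for a joint (plus the reference
   position and, optionally, the previous merged position as auxiliary
   candidates) are clustered with searching area ``eps`` and minimum
   neighbor count ``N_c = 1``; the largest cluster wins and the merged
   position is the centroid of its *sensor* candidates only.
3. *Kalman tracking* — a per-joint constant-position Kalman filter
   (``A = H = I``, isotropic noise ``Q = q I``, ``R = r I``) smooths the
   merged trajectory; the predicted state is the tracked output.

Pipeline variants: A1 = plain per-joint average; A2 = A1 + arrangement;
A3 = arrangement + DBSCAN merge; A4 = A3 + previous-position smoothing
candidate; A5 = A4 + Kalman tracking.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    JOINTS,
    JOINT_INDEX,
    MIRROR_PAIRS,
    Confidence,
    JointObservation,
    SkeletonFrame,
    SkeletonTrack,
    frames_to_track,
    stack_tracks,
)

__all__ = [
    "NOISE",
    "VARIANTS",
    "KalmanConfig",
    "FusionConfig",
    "PairCheckResult",
    "ClusterLabeling",
    "MergedJoint",
    "JointStatus",
    "KalmanJointState",
    "MergedTrack",
    "reference_position",
    "check_pair",
    "arrange_frame",
    "arrange_arrays",
    "dbscan",
    "merge_joint",
    "kalman_step",
    "fuse_frame",
    "fuse_sequence",
]

#: DBSCAN label of points assigned to no cluster
NOISE = -1

VARIANTS = ("A1", "A2", "A3", "A4", "A5")


@dataclass(frozen=True)
class KalmanConfig:
    """Noise variances of the per-joint tracker (defaults per the method)."""

    q: float = 0.01
    r: float = 1.0

    def __post_init__(self):
        if self.q <= 0 or self.r <= 0:
            raise ValueError("q and r must be positive")

    @property
    def steady_state_gain(self) -> float:
        """Per-axis steady-state Kalman gain (scalar Riccati closed form)."""
        m = (self.q + np.sqrt(self.q**2 + 4 * self.q * self.r)) / 2.0
        return m / (m + self.r)


@dataclass(frozen=True)
class FusionConfig:
    """Pipeline variant and its parameters (``eps_mm`` is the DBSCAN searching area)."""

    variant: str = "A5"
    eps_mm: float = 100.0
    min_neighbors: int = 1
    use_reference_candidate: bool = True
    use_previous_candidate: bool | None = None  # None: derived from variant
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    max_coast_frames: int = 30

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.eps_mm <= 0:
            raise ValueError("eps_mm must be positive")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")

    @property
    def arrangement_enabled(self) -> bool:
        return self.variant in ("A2", "A3", "A4", "A5")

    @property
    def clustering_enabled(self) -> bool:
        return self.variant in ("A3", "A4", "A5")

    @property
    def previous_enabled(self) -> bool:
        if self.use_previous_candidate is not None:
            return self.use_previous_candidate and self.clustering_enabled
        return self.variant in ("A4", "A5")

    @property
    def kalman_enabled(self) -> bool:
        return self.variant == "A5"


@dataclass
class PairCheckResult:
    ref_right: np.ndarray
    ref_left: np.ndarray
    d_correct: float
    d_wrong: float
    swapped: bool


@dataclass
class ClusterLabeling:
    """Cluster ids 1..k per candidate; ``NOISE`` (-1) marks unclustered points."""

    labels: np.ndarray
    k: int


class JointStatus(IntEnum):
    MISSING = 0
    PREDICTED = 1
    MERGED = 2


@dataclass
class MergedJoint:
    position: np.ndarray
    n_contributing: int
    status: JointStatus


@dataclass
class KalmanJointState:
    """Per-joint tracker state; covariances in mm^2."""

    x_post: np.ndarray = field(default_factory=lambda: np.zeros(3))
    p_post: np.ndarray = field(default_factory=lambda: np.eye(3))
    x_pred: np.ndarray = field(default_factory=lambda: np.zeros(3))
    p_pred: np.ndarray = field(default_factory=lambda: np.eye(3))
    last_gain: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    initialized: bool = False


@dataclass
class MergedTrack:
    """Fused skeleton sequence: positions (F, 16, 3) mm, per-joint status codes."""

    frame_index: np.ndarray
    positions: np.ndarray
    status: np.ndarray
    n_contributing: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def to_skeleton_track(self, sensor_id: str = "merged") -> SkeletonTrack:
        conf = np.where(self.status == JointStatus.MERGED, int(Confidence.MEDIUM),
                        np.where(self.status == JointStatus.PREDICTED, int(Confidence.LOW), 0))
        return SkeletonTrack(sensor_id, self.frame_index, self.positions, conf.astype(np.int8))


# ---------------------------------------------------------------------------
# arrangement


def reference_position(candidates: Sequence[JointObservation]) -> np.ndarray | None:
    """Confidence-weighted reference: mean of medium candidates, else lows, else None."""
    for level in (Confidence.MEDIUM, Confidence.LOW):
        pts = [c.position for c in candidates if c.confidence == level]
        if pts:
            return np.mean(pts, axis=0)
    return None


def check_pair(
    ref_r: np.ndarray, ref_l: np.ndarray, target_r: np.ndarray, target_l: np.ndarray
) -> PairCheckResult:
    """Distance rule flagging a left/right label swap for one sensor's pair.

    ``d_correct`` is the distance from the right-side reference to the
    sensor's right joint, ``d_wrong`` to its left joint; the pair is flagged
    swapped when ``d_correct > d_wrong`` (ties are never swapped).
    """
    ref_r = np.asarray(ref_r, dtype=float)
    ref_l = np.asarray(ref_l, dtype=float)
    d_correct = float(np.linalg.norm(ref_r - np.asarray(target_r, dtype=float)))
    d_wrong = float(np.linalg.norm(ref_r - np.asarray(target_l, dtype=float)))
    return PairCheckResult(ref_r, ref_l, d_correct, d_wrong, swapped=d_correct > d_wrong)


def _conf_mean(pos_j: np.ndarray, conf_j: np.ndarray) -> np.ndarray:
    """Per-frame reference positions for one joint.

    ``pos_j`` is (S, F, 3), ``conf_j`` is (S, F); returns (F, 3) with NaN
    where no sensor reports the joint.
    """
    F = pos_j.shape[1]
    out = np.full((F, 3), np.nan)
    unset = np.ones(F, dtype=bool)
    for level in (int(Confidence.MEDIUM), int(Confidence.LOW)):
        mask = conf_j == level
        cnt = mask.sum(axis=0)
        sel = unset & (cnt > 0)
        if np.any(sel):
            s = np.where(mask[..., None], pos_j, 0.0).sum(axis=0)
            out[sel] = s[sel] / cnt[sel, None]
            unset &= ~sel
    return out


def arrange_arrays(pos: np.ndarray, conf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized arrangement over (S, F, 16, 3) positions / (S, F, 16) confidences.

    Returns corrected copies; sensors missing one member of a pair are skipped.
    """
    pos = pos.copy()
    conf = conf.copy()
    for l_idx, r_idx in MIRROR_PAIRS:
        ref_r = _conf_mean(pos[:, :, r_idx], conf[:, :, r_idx])  # (F, 3)
        both = (conf[:, :, l_idx] > 0) & (conf[:, :, r_idx] > 0)  # (S, F)
        have_ref = np.isfinite(ref_r[:, 0])  # (F,)
        d_correct = np.linalg.norm(pos[:, :, r_idx] - ref_r[None], axis=-1)
        d_wrong = np.linalg.norm(pos[:, :, l_idx] - ref_r[None], axis=-1)
        swap = both & have_ref[None] & (d_correct > d_wrong)
        if np.any(swap):
            s_i, f_i = np.nonzero(swap)
            tmp = pos[s_i, f_i, l_idx].copy()
            pos[s_i, f_i, l_idx] = pos[s_i, f_i, r_idx]
            pos[s_i, f_i, r_idx] = tmp
            tmpc = conf[s_i, f_i, l_idx].copy()
            conf[s_i, f_i, l_idx] = conf[s_i, f_i, r_idx]
            conf[s_i, f_i, r_idx] = tmpc
    return pos, conf


def arrange_frame(frames: Sequence[SkeletonFrame]) -> list[SkeletonFrame]:
    """Correct misoriented left/right labels across one synchronized frame set."""
    frames = list(frames)
    if not frames:
        return []
    fi = frames[0].frame_index
    if any(f.frame_index != fi for f in frames):
        raise ValueError("arrange_frame requires frames sharing one frame_index")
    S, J = len(frames), len(JOINTS)
    pos = np.full((S, 1, J, 3), np.nan)
    conf = np.zeros((S, 1, J), dtype=np.int8)
    for s, f in enumerate(frames):
        for name, obs in f.joints.items():
            j = JOINT_INDEX[name]
            conf[s, 0, j] = int(obs.confidence)
            if obs.confidence != Confidence.NONE:
                pos[s, 0, j] = obs.position
    pos, conf = arrange_arrays(pos, conf)
    out = []
    for s, f in enumerate(frames):
        joints = {}
        for name, obs in f.joints.items():
            j = JOINT_INDEX[name]
            c = Confidence(int(conf[s, 0, j]))
            if c == Confidence.NONE:
                joints[name] = obs
            else:
                joints[name] = JointObservation(pos[s, 0, j].copy(), c)
        out.append(SkeletonFrame(f.sensor_id, f.frame_index, joints))
    return out


# ---------------------------------------------------------------------------
# DBSCAN


def dbscan(points: np.ndarray, eps_mm: float, min_neighbors: int = 1) -> ClusterLabeling:
    """Density clustering with closed-ball neighborhoods.

    A point is core when its eps-neighborhood (Euclidean, ``distance <= eps``,
    the point itself included) holds at least ``min_neighbors`` points; core
    points seed clusters grown by queue expansion, remaining points are NOISE.
    """
    if eps_mm <= 0:
        raise ValueError("eps_mm must be positive")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterLabeling(labels=np.empty(0, dtype=int), k=0)
    if pts.ndim != 2:
        raise ValueError("points must be (n, d)")
    n = pts.shape[0]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    within = d2 <= eps_mm * eps_mm
    neighbors = [np.flatnonzero(within[i]) for i in range(n)]
    UNASSIGNED = 0
    labels = np.full(n, UNASSIGNED, dtype=int)
    k = 0
    for i in range(n):
        if labels[i] != UNASSIGNED:
            continue
        if len(neighbors[i]) >= min_neighbors:
            k += 1
            labels[i] = k
            queue = deque(neighbors[i])
            while queue:
                z = queue.popleft()
                if labels[z] == UNASSIGNED:
                    labels[z] = k
                    if len(neighbors[z]) >= min_neighbors:
                        queue.extend(neighbors[z])
        else:
            labels[i] = NOISE
    return ClusterLabeling(labels=labels, k=k)


# ---------------------------------------------------------------------------
# merging


def _merge_candidates(
    cands: np.ndarray,
    reference: np.ndarray | None,
    previous: np.ndarray | None,
    eps_mm: float,
    min_neighbors: int,
) -> tuple[np.ndarray, int, JointStatus]:
    """Largest-cluster merge of one joint's candidates; returns (pos, n, status)."""
    n = len(cands)
    if n == 0:
        if previous is not None:
            return np.asarray(previous, dtype=float), 0, JointStatus.PREDICTED
        return np.full(3, np.nan), 0, JointStatus.MISSING
    extra = []
    ref_idx = prev_idx = -1
    if reference is not None:
        ref_idx = n + len(extra)
        extra.append(np.asarray(reference, dtype=float))
    if previous is not None:
        prev_idx = n + len(extra)
        extra.append(np.asarray(previous, dtype=float))
    pts = np.vstack([cands] + [e[None] for e in extra]) if extra else np.asarray(cands, dtype=float)
    labeling = dbscan(pts, eps_mm, min_neighbors)
    labels = labeling.labels
    if labeling.k == 0:
        if previous is not None:
            return np.asarray(previous, dtype=float), 0, JointStatus.PREDICTED
        return np.full(3, np.nan), 0, JointStatus.MISSING
    sizes = np.bincount(labels[labels > 0], minlength=labeling.k + 1)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        has_sensor = [np.any(labels[:n] == c) for c in best]
        if any(has_sensor):
            best = best[np.asarray(has_sensor)]
    if len(best) > 1 and ref_idx >= 0 and labels[ref_idx] in best:
        best = np.array([labels[ref_idx]])
    if len(best) > 1 and prev_idx >= 0 and labels[prev_idx] in best:
        best = np.array([labels[prev_idx]])
    if len(best) > 1 and previous is not None:
        cents = np.array([pts[labels == c].mean(axis=0) for c in best])
        best = best[[int(np.argmin(np.linalg.norm(cents - previous, axis=1)))]]
    win = int(best[0])
    members = labels[:n] == win
    if not np.any(members):
        if previous is not None:
            return np.asarray(previous, dtype=float), 0, JointStatus.PREDICTED
        return np.full(3, np.nan), 0, JointStatus.MISSING
    return cands[members].mean(axis=0), int(members.sum()), JointStatus.MERGED


def merge_joint(
    sensor_candidates: Sequence[np.ndarray],
    reference: np.ndarray | None,
    previous: np.ndarray | None,
    config: FusionConfig,
) -> MergedJoint:
    """Merge one joint's cross-sensor candidates into a single position.

    The reference and previous positions take part in the clustering only
    (anchoring consensus / smoothing); the merged position is the centroid of
    the winning cluster's sensor candidates.  Largest-cluster ties prefer, in
    order: clusters with sensor members, the reference's cluster, the
    previous position's cluster, the cluster nearest the previous position,
    the lowest cluster id.
    """
    cands = np.asarray(sensor_candidates, dtype=float).reshape(-1, 3)
    ref = reference if config.use_reference_candidate else None
    prev = previous if config.previous_enabled else None
    pos, ncontrib, status = _merge_candidates(cands, ref, prev, config.eps_mm, config.min_neighbors)
    return MergedJoint(pos, ncontrib, status)


# ---------------------------------------------------------------------------
# Kalman tracking


def kalman_step(
    state: KalmanJointState, measurement: np.ndarray | None, config: KalmanConfig
) -> tuple[KalmanJointState, np.ndarray]:
    """One predict(-update) cycle of the constant-position joint tracker.

    The returned tracked position is the predicted state (the posterior from
    the previous step propagated through ``A = I``); a missing measurement
    skips the correction.  The very first call initializes the posterior at
    the measurement, which is then returned unchanged.
    """
    q, r = config.q, config.r
    I = np.eye(3)
    if not state.initialized:
        if measurement is None:
            raise ValueError("cannot track: tracker uninitialized and no measurement")
        z = np.asarray(measurement, dtype=float)
        new = KalmanJointState(
            x_post=z.copy(), p_post=I.copy(), x_pred=z.copy(), p_pred=I.copy(),
            last_gain=np.zeros((3, 3)), initialized=True,
        )
        return new, z.copy()
    x_pred = state.x_post.copy()  # A = I
    p_pred = state.p_post + q * I
    tracked = x_pred.copy()
    if measurement is not None:
        z = np.asarray(measurement, dtype=float)
        K = p_pred @ np.linalg.inv(p_pred + r * I)  # H = I
        x_post = x_pred + K @ (z - x_pred)
        p_post = (I - K) @ p_pred
        p_post = 0.5 * (p_post + p_post.T)
        new = KalmanJointState(x_post, p_post, x_pred, p_pred, K, True)
    else:
        new = KalmanJointState(x_pred.copy(), p_pred.copy(), x_pred, p_pred,
                               state.last_gain, True)
    return new, tracked


# ---------------------------------------------------------------------------
# frame / sequence fusion


def _frames_to_arrays(frames: Sequence[SkeletonFrame]) -> tuple[np.ndarray, np.ndarray]:
    S, J = len(frames), len(JOINTS)
    pos = np.full((S, J, 3), np.nan)
    conf = np.zeros((S, J), dtype=np.int8)
    for s, f in enumerate(frames):
        for name, obs in f.joints.items():
            j = JOINT_INDEX[name]
            conf[s, j] = int(obs.confidence)
            if obs.confidence != Confidence.NONE:
                pos[s, j] = obs.position
    return pos, conf


def fuse_frame(
    frames: Sequence[SkeletonFrame],
    trackers: dict[str, KalmanJointState] | None = None,
    prev_merged: Mapping[str, np.ndarray] | None = None,
    config: FusionConfig = FusionConfig(),
) -> tuple[dict[str, MergedJoint], dict[str, KalmanJointState]]:
    """Fuse one synchronized set of per-sensor frames into a merged skeleton."""
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame list: no skeleton to merge")
    fi = frames[0].frame_index
    if any(f.frame_index != fi for f in frames):
        raise ValueError("frames passed to fuse_frame must share one frame_index")
    trackers = dict(trackers) if trackers else {}
    prev_merged = dict(prev_merged) if prev_merged else {}
    pos, conf = _frames_to_arrays(frames)
    if config.arrangement_enabled:
        pos4, conf4 = arrange_arrays(pos[:, None], conf[:, None])
        pos, conf = pos4[:, 0], conf4[:, 0]
    merged: dict[str, MergedJoint] = {}
    for j, name in enumerate(JOINTS):
        have = conf[:, j] > 0
        cands = pos[have, j]
        prev = prev_merged.get(name)
        if not config.clustering_enabled:
            if len(cands):
                mj = MergedJoint(cands.mean(axis=0), len(cands), JointStatus.MERGED)
            else:
                mj = MergedJoint(np.full(3, np.nan), 0, JointStatus.MISSING)
        else:
            ref = _conf_mean(pos[:, None, j], conf[:, None, j])[0]
            ref = ref if np.isfinite(ref[0]) else None
            mj = merge_joint(cands, ref, prev, config)
        if config.kalman_enabled:
            st = trackers.get(name, KalmanJointState())
            z = mj.position if mj.status == JointStatus.MERGED else None
            if st.initialized or z is not None:
                st, tracked = kalman_step(st, z, config.kalman)
                trackers[name] = st
                if mj.status != JointStatus.MISSING:
                    mj = replace(mj, position=tracked)
        merged[name] = mj
    return merged, trackers


def fuse_sequence(
    streams: Mapping[str, SkeletonTrack] | Mapping[str, Sequence[SkeletonFrame]] | Iterable[SkeletonTrack],
    config: FusionConfig = FusionConfig(),
) -> MergedTrack:
    """Stateful left-to-right fusion of synchronized multi-sensor streams.

    Streams are aligned on ``frame_index``; per-joint Kalman trackers are
    initialized at the first merged measurement.  A joint coasting on
    predictions for more than ``config.max_coast_frames`` consecutive steps
    is flagged missing instead of extrapolated forever, and its tracker is
    re-initialized when measurements resume.
    """
    tracks = _normalize_streams(streams)
    ids, idx, pos, conf = stack_tracks(tracks)
    S, F, J = pos.shape[:3]
    if config.arrangement_enabled:
        pos, conf = arrange_arrays(pos, conf)
    out_pos = np.full((F, J, 3), np.nan)
    out_status = np.zeros((F, J), dtype=np.int8)
    out_n = np.zeros((F, J), dtype=np.int16)

    if not config.clustering_enabled:  # A1 / A2: plain average
        have = conf > 0  # (S, F, J)
        cnt = have.sum(axis=0)
        s = np.where(have[..., None], np.nan_to_num(pos), 0.0).sum(axis=0)
        nz = cnt > 0
        out_pos[nz] = s[nz] / cnt[nz, None]
        out_status[nz] = JointStatus.MERGED
        out_n = cnt.astype(np.int16)
        return MergedTrack(idx, out_pos, out_status, out_n)

    refs = np.empty((F, J, 3))
    for j in range(J):
        refs[:, j] = _conf_mean(pos[:, :, j], conf[:, :, j])

    eps, min_nb = config.eps_mm, config.min_neighbors
    use_prev = config.previous_enabled
    kal = config.kalman_enabled
    prev = [None] * J  # previous merged centroid (pre-filter)
    coast = np.zeros(J, dtype=int)
    trackers = [KalmanJointState() for _ in range(J)] if kal else None
    for f in range(F):
        conf_f = conf[:, f]
        pos_f = pos[:, f]
        for j in range(J):
            have = conf_f[:, j] > 0
            cands = pos_f[have, j]
            ref = refs[f, j]
            ref_ok = ref if np.isfinite(ref[0]) else None
            p = prev[j] if use_prev else None
            mpos, ncontrib, status = _merge_candidates(cands, ref_ok, p, eps, min_nb)
            if status == JointStatus.MERGED:
                prev[j] = mpos
                coast[j] = 0
            elif status == JointStatus.PREDICTED:
                coast[j] += 1
                if coast[j] > config.max_coast_frames:
                    status = JointStatus.MISSING
                    mpos = np.full(3, np.nan)
                    prev[j] = None
            if kal:
                st = trackers[j]
                if status == JointStatus.MERGED:
                    st, tracked = kalman_step(st, mpos, config.kalman)
                    trackers[j] = st
                    mpos = tracked
                elif status == JointStatus.PREDICTED and st.initialized:
                    st, tracked = kalman_step(st, None, config.kalman)
                    trackers[j] = st
                    mpos = tracked
                elif status == JointStatus.MISSING:
                    trackers[j] = KalmanJointState()  # re-init on return
            out_pos[f, j] = mpos
            out_status[f, j] = status
            out_n[f, j] = ncontrib
    return MergedTrack(idx, out_pos, out_status, out_n)


def _normalize_streams(streams) -> dict[str, SkeletonTrack]:
    if isinstance(streams, Mapping):
        out = {}
        for sid, v in streams.items():
            out[sid] = v if isinstance(v, SkeletonTrack) else frames_to_track(v, sid)
        return out
    tracks = list(streams)
    if not all(isinstance(t, SkeletonTrack) for t in tracks):
        raise TypeError("streams must be SkeletonTracks or a mapping of frames")
    return {t.sensor_id: t for t in tracks}
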