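"""Synthetic multi-sensor gesture benchmark.

Ground-truth motion comes from analytic kinematic templates of six gestures
(both hands up/down, jump, squat, lunge, walking, free movement in a
standing pose) driven by joint angles on a fixed-segment-length body model,
so bone lengths are constant by construction.  The corruption model then
emulates what a ring of depth sensors actually delivers: every joint gets
isotropic Gaussian jitter; joints whose outward normal faces away from a
sensor are demoted to *low* confidence and hit by large occlusion outliers
with some probability; left/right pairs may be swapped (misorientation,
demoting the pair to low); joints drop out entirely (*none*) at random.

The templates are kinematic toys, not biomechanics: their job is to
exercise the fusion pipeline under motion, occlusion and label noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .calibration import RigidTransform
from .core import JOINTS, JOINT_INDEX, MIRROR_PAIRS, SkeletonTrack

__all__ = [
    "GESTURES",
    "DEFAULT_SEGMENTS_MM",
    "GestureSpec",
    "Sensor",
    "SensorRig",
    "NoiseModel",
    "generate_gesture",
    "observe",
    "make_benchmark",
    "default_rig",
    "default_benchmark",
]

GESTURES = ("hands_up_down", "jump", "squat", "lunge", "walking", "random_movement")

#: default limb-segment lengths, mm (adult standing height ~1.75 m)
DEFAULT_SEGMENTS_MM: dict[str, float] = {
    "pelvis_to_spine": 200.0,
    "spine_to_neck": 300.0,
    "neck_to_head": 150.0,
    "neck_to_shoulder": 180.0,
    "pelvis_to_hip": 90.0,
    "upper_arm": 280.0,
    "forearm": 250.0,
    "thigh": 420.0,
    "shank": 400.0,
}

_PELVIS_HEIGHT = 900.0  # standing pelvis height: hip + thigh + shank + ankle clearance


@dataclass
class GestureSpec:
    """One ground-truth capture: gesture template, duration and scale."""

    gesture: str
    n_frames: int = 1000
    frame_rate_hz: float = 30.0
    params: dict = field(default_factory=dict)
    segments_mm: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENTS_MM))

    def __post_init__(self):
        if self.gesture not in GESTURES:
            raise ValueError(f"unknown gesture {self.gesture!r}; expected one of {GESTURES}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(v <= 0 for v in self.segments_mm.values()):
            raise ValueError("segment lengths must be positive")


@dataclass
class Sensor:
    sensor_id: str
    pose: RigidTransform  # camera -> global
    hfov_deg: float = 120.0
    max_range_mm: float = 6000.0

    @property
    def position(self) -> np.ndarray:
        return self.pose.translation

    @property
    def optical_axis(self) -> np.ndarray:
        return self.pose.rotation[:, 2]  # camera +z in global coords


@dataclass
class SensorRig:
    sensors: list[Sensor]
    reference_sensor: Sensor | None = None

    def __post_init__(self):
        if not self.sensors:
            raise ValueError("a rig needs at least one sensor")


@dataclass
class NoiseModel:
    """Per-sensor corruption parameters (probabilities per joint per frame)."""

    jitter_sigma_mm: float = 5.0
    outlier_prob: float = 0.15
    outlier_scale_mm: float = 300.0
    swap_prob: float = 0.0
    dropout_prob: float = 0.01
    occlusion_angle_deg: float = 90.0  # <= 0 treats every joint as occluded
    seed: int = 0

    def __post_init__(self):
        for p in (self.outlier_prob, self.swap_prob, self.dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.jitter_sigma_mm < 0 or self.outlier_scale_mm < 0:
            raise ValueError("scales must be non-negative")


# ---------------------------------------------------------------------------
# kinematic templates


def _heading_rot(psi: np.ndarray) -> np.ndarray:
    """(F, 3, 3) rotation about z by heading angle psi (radians)."""
    c, s = np.cos(psi), np.sin(psi)
    R = np.zeros((len(psi), 3, 3))
    R[:, 0, 0], R[:, 0, 1] = c, -s
    R[:, 1, 0], R[:, 1, 1] = s, c
    R[:, 2, 2] = 1.0
    return R


def _sagittal(R: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Unit vector at `angle` from straight-down, rotating forward, per frame."""
    local = np.stack([np.sin(angle), np.zeros_like(angle), -np.cos(angle)], axis=-1)
    return np.einsum("fij,fj->fi", R, local)


def _leg_ik(hip: np.ndarray, ankle: np.ndarray, forward: np.ndarray,
            l_thigh: float, l_shank: float) -> np.ndarray:
    """Knee position from pinned hip and ankle (two-link planar IK).

    The knee lies in the plane spanned by the hip-ankle axis and the forward
    direction, offset toward forward; segment lengths are preserved exactly.
    """
    d_vec = ankle - hip
    d = np.linalg.norm(d_vec, axis=-1)
    reach = l_thigh + l_shank
    if np.any(d > reach + 1e-6):  # straight leg (d == reach) is allowed
        raise ValueError("leg IK target out of reach; reduce squat/lunge amplitude")
    u = d_vec / d[:, None]
    a = (l_thigh**2 - l_shank**2 + d**2) / (2 * d)
    h = np.sqrt(np.maximum(l_thigh**2 - a**2, 0.0))
    f = forward - np.sum(forward * u, axis=-1, keepdims=True) * u
    f = f / np.linalg.norm(f, axis=-1, keepdims=True)
    return hip + a[:, None] * u + h[:, None] * f


def _smooth_signals(rng: np.random.Generator, t: np.ndarray, n: int,
                    fmin: float = 0.1, fmax: float = 0.4) -> np.ndarray:
    """n smooth pseudo-random unit-amplitude signals (sums of 3 sinusoids)."""
    out = np.zeros((n, len(t)))
    for i in range(n):
        for _ in range(3):
            f = rng.uniform(fmin, fmax)
            phase = rng.uniform(0, 2 * np.pi)
            out[i] += np.sin(2 * np.pi * f * t + phase)
        out[i] /= 3.0
    return out


def generate_gesture(spec: GestureSpec) -> SkeletonTrack:
    """Ground-truth skeleton sequence for one gesture (global frame, mm).

    Deterministic; ``random_movement`` draws its smooth angle trajectories
    from ``params['seed']`` (default 0).  Bone lengths are constant across
    frames by construction.
    """
    g = spec.gesture
    seg = spec.segments_mm
    F = spec.n_frames
    t = np.arange(F) / spec.frame_rate_hz
    p = spec.params

    pelvis = np.zeros((F, 3))
    pelvis[:, 2] = _PELVIS_HEIGHT
    psi = np.zeros(F)  # heading about z; subject faces +x
    # joint angles, radians; arms: elevation from straight-down (sagittal),
    # elbow flexion; legs: hip flexion from straight-down, knee flexion
    arm_l = np.full(F, np.deg2rad(10.0))
    arm_r = np.full(F, np.deg2rad(10.0))
    elbow_l = np.full(F, np.deg2rad(10.0))
    elbow_r = np.full(F, np.deg2rad(10.0))
    hip_l = np.zeros(F)
    hip_r = np.zeros(F)
    knee_l = np.zeros(F)
    knee_r = np.zeros(F)
    pinned_ankles: tuple[np.ndarray, np.ndarray] | None = None  # (left, right)

    leg_len = seg["thigh"] + seg["shank"]
    stand_ankle_z = _PELVIS_HEIGHT - leg_len  # ankle clearance above floor

    if g == "hands_up_down":
        period = p.get("period_s", 4.0)
        mid = np.deg2rad(p.get("mid_deg", 80.0))
        amp = np.deg2rad(p.get("amplitude_deg", 75.0))
        sweep = mid + amp * np.sin(2 * np.pi * t / period)
        arm_l = arm_r = sweep
        elbow_l = elbow_r = np.full(F, np.deg2rad(5.0))
    elif g == "jump":
        period = p.get("period_s", 1.2)
        amp = p.get("amplitude_mm", 300.0)
        lift = amp * np.maximum(0.0, np.sin(2 * np.pi * t / period)) ** 2
        pelvis[:, 2] += lift
        arm_l = arm_r = np.full(F, np.deg2rad(160.0))
    elif g == "squat":
        period = p.get("period_s", 4.0)
        amp = p.get("amplitude_mm", 300.0)
        drop = 0.5 * amp * (1 - np.cos(2 * np.pi * t / period))
        pelvis[:, 2] -= drop
        arm_l = arm_r = np.deg2rad(10.0) + (drop / max(amp, 1e-9)) * np.deg2rad(70.0)
        la = np.tile([0.0, seg["pelvis_to_hip"], stand_ankle_z], (F, 1))
        ra = np.tile([0.0, -seg["pelvis_to_hip"], stand_ankle_z], (F, 1))
        pinned_ankles = (la, ra)
    elif g == "lunge":
        period = p.get("period_s", 4.0)
        amp = p.get("amplitude_mm", 200.0)
        split = p.get("split_mm", 300.0)
        drop = 0.5 * amp * (1 - np.cos(2 * np.pi * t / period))
        pelvis[:, 2] -= 150.0 + drop  # lunge stance keeps the pelvis low throughout
        la = np.tile([-split, seg["pelvis_to_hip"], stand_ankle_z], (F, 1))
        ra = np.tile([split, -seg["pelvis_to_hip"], stand_ankle_z], (F, 1))
        pinned_ankles = (la, ra)
    elif g == "walking":
        speed = p.get("speed_mm_s", 1200.0)
        stride = p.get("stride_period_s", 1.0)
        mode = p.get("mode", "travel")
        swing = np.deg2rad(p.get("hip_swing_deg", 25.0))
        phase = 2 * np.pi * t / stride
        hip_l = swing * np.sin(phase)
        hip_r = -swing * np.sin(phase)
        knee_l = np.deg2rad(25.0) * np.maximum(0.0, np.sin(phase + np.pi / 2))
        knee_r = np.deg2rad(25.0) * np.maximum(0.0, np.sin(phase - np.pi / 2))
        arm_l = np.deg2rad(10.0) + np.deg2rad(12.0) * np.sin(phase + np.pi)
        arm_r = np.deg2rad(10.0) + np.deg2rad(12.0) * np.sin(phase)
        if mode == "travel":
            pelvis[:, 0] += speed * t
        elif mode == "in_place":
            pelvis[:, 2] += p.get("bob_mm", 25.0) * np.sin(2 * phase)
        else:
            raise ValueError(f"unknown walking mode {mode!r}")
    elif g == "random_movement":
        rng = np.random.default_rng(p.get("seed", 0))
        sig = _smooth_signals(rng, t, 8)
        psi = np.deg2rad(20.0) * sig[0]
        pelvis[:, 0] += 50.0 * sig[1]
        pelvis[:, 1] += 50.0 * sig[2]
        arm_l = np.deg2rad(45.0) + np.deg2rad(35.0) * sig[3]
        arm_r = np.deg2rad(45.0) + np.deg2rad(35.0) * sig[4]
        elbow_l = np.deg2rad(25.0) + np.deg2rad(20.0) * sig[5]
        elbow_r = np.deg2rad(25.0) + np.deg2rad(20.0) * sig[6]
        hip_l = np.deg2rad(5.0) * sig[7]
        hip_r = -np.deg2rad(5.0) * sig[7]

    R = _heading_rot(psi)
    forward = R[:, :, 0]
    left = R[:, :, 1]
    up = np.array([0.0, 0.0, 1.0])

    pos = np.empty((F, len(JOINTS), 3))

    def put(name: str, v: np.ndarray) -> None:
        pos[:, JOINT_INDEX[name]] = v

    spine = pelvis + seg["pelvis_to_spine"] * up
    neck = spine + seg["spine_to_neck"] * up
    head = neck + seg["neck_to_head"] * up
    put("pelvis", pelvis)
    put("spine_naval", spine)
    put("neck", neck)
    put("head", head)
    sh_l = neck + seg["neck_to_shoulder"] * left
    sh_r = neck - seg["neck_to_shoulder"] * left
    put("shoulder_L", sh_l)
    put("shoulder_R", sh_r)
    hip_lp = pelvis + seg["pelvis_to_hip"] * left
    hip_rp = pelvis - seg["pelvis_to_hip"] * left
    put("hip_L", hip_lp)
    put("hip_R", hip_rp)

    el_l = sh_l + seg["upper_arm"] * _sagittal(R, arm_l)
    el_r = sh_r + seg["upper_arm"] * _sagittal(R, arm_r)
    put("elbow_L", el_l)
    put("elbow_R", el_r)
    put("wrist_L", el_l + seg["forearm"] * _sagittal(R, arm_l + elbow_l))
    put("wrist_R", el_r + seg["forearm"] * _sagittal(R, arm_r + elbow_r))

    if pinned_ankles is not None:
        ank_l, ank_r = pinned_ankles
        kn_l = _leg_ik(hip_lp, ank_l, forward, seg["thigh"], seg["shank"])
        kn_r = _leg_ik(hip_rp, ank_r, forward, seg["thigh"], seg["shank"])
    else:
        kn_l = hip_lp + seg["thigh"] * _sagittal(R, hip_l)
        kn_r = hip_rp + seg["thigh"] * _sagittal(R, hip_r)
        ank_l = kn_l + seg["shank"] * _sagittal(R, hip_l - knee_l)
        ank_r = kn_r + seg["shank"] * _sagittal(R, hip_r - knee_r)
    put("knee_L", kn_l)
    put("knee_R", kn_r)
    put("ankle_L", ank_l)
    put("ankle_R", ank_r)

    conf = np.full((F, len(JOINTS)), 2, dtype=np.int8)
    return SkeletonTrack("truth", np.arange(F), pos, conf)


# ---------------------------------------------------------------------------
# sensor observation


def default_rig(n_sensors: int = 4, radius_mm: float = 2500.0, height_mm: float = 1000.0,
                with_reference: bool = True) -> SensorRig:
    """Sensors evenly spaced on a circle around the capture spot, aimed at it."""
    target = np.array([0.0, 0.0, 1000.0])
    sensors = []
    for i in range(n_sensors):
        ang = 2 * np.pi * i / n_sensors + np.pi / n_sensors  # offset so none is dead-ahead
        pos_s = np.array([radius_mm * np.cos(ang), radius_mm * np.sin(ang), height_mm])
        sensors.append(Sensor(f"cam{i}", _look_at_pose(pos_s, target)))
    ref = None
    if with_reference:
        ref_pos = np.array([radius_mm, 0.0, height_mm])
        ref = Sensor("best_view", _look_at_pose(ref_pos, target))
    return SensorRig(sensors=sensors, reference_sensor=ref)


def _look_at_pose(position: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Camera pose (x right, y down, z forward) looking at `target`."""
    z = target - position
    z = z / np.linalg.norm(z)
    world_up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, world_up)
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / nx
    y = np.cross(z, x)
    return RigidTransform(np.column_stack([x, y, z]), position)


def _facing(positions: np.ndarray) -> np.ndarray:
    """(F, 3) horizontal facing direction from the shoulder line."""
    d = positions[:, JOINT_INDEX["shoulder_L"]] - positions[:, JOINT_INDEX["shoulder_R"]]
    f = np.cross(d, np.array([0.0, 0.0, 1.0]))
    f[:, 2] = 0.0
    return f / np.linalg.norm(f, axis=-1, keepdims=True)


def _joint_normals(positions: np.ndarray) -> np.ndarray:
    """(F, J, 3) outward joint normals: horizontal radial from the body axis,
    facing direction for near-axis (midline) joints."""
    F, J = positions.shape[:2]
    pelvis = positions[:, JOINT_INDEX["pelvis"]]
    r = positions - pelvis[:, None]
    r[..., 2] = 0.0
    norm = np.linalg.norm(r, axis=-1)
    facing = _facing(positions)
    out = np.where(norm[..., None] > 50.0, r / np.maximum(norm, 1e-9)[..., None],
                   np.broadcast_to(facing[:, None], (F, J, 3)))
    return out


def observe(
    gt: SkeletonTrack,
    rig: SensorRig,
    noise: NoiseModel,
    output_frame: str = "global",
    include_reference: bool = False,
) -> dict[str, SkeletonTrack]:
    """Corrupt ground truth into per-sensor streams (reproducible given seed).

    With ``output_frame='sensor'`` the streams are expressed in each camera's
    own coordinates (use the calibration stage to bring them back); with
    ``'global'`` they stay in the calibrated common frame.
    """
    if output_frame not in ("global", "sensor"):
        raise ValueError("output_frame must be 'global' or 'sensor'")
    sensors = list(rig.sensors)
    if include_reference and rig.reference_sensor is not None:
        sensors = sensors + [rig.reference_sensor]
    F, J = gt.positions.shape[:2]
    normals = _joint_normals(gt.positions)
    cos_thr = np.cos(np.deg2rad(noise.occlusion_angle_deg))
    rng = np.random.default_rng(noise.seed)
    out: dict[str, SkeletonTrack] = {}
    for sensor in sensors:
        pos = gt.positions.copy()
        conf = np.full((F, J), 2, dtype=np.int8)
        view = sensor.position[None, None] - pos
        dist = np.linalg.norm(view, axis=-1)
        view_dir = view / np.maximum(dist, 1e-9)[..., None]
        if noise.occlusion_angle_deg <= 0:
            occluded = np.ones((F, J), dtype=bool)
        else:
            cosang = np.sum(normals * view_dir, axis=-1)
            occluded = cosang < cos_thr  # angle strictly beyond threshold
        conf[occluded] = 1
        # occlusion outliers: uniform direction, magnitude ~ outlier scale
        hit = occluded & (rng.random((F, J)) < noise.outlier_prob)
        n_hit = int(hit.sum())
        if n_hit:
            direc = rng.normal(size=(n_hit, 3))
            direc /= np.linalg.norm(direc, axis=-1, keepdims=True)
            mag = rng.uniform(0.5, 1.5, size=n_hit) * noise.outlier_scale_mm
            pos[hit] += direc * mag[:, None]
        pos += rng.normal(scale=noise.jitter_sigma_mm, size=pos.shape)
        if noise.swap_prob > 0:
            for l_idx, r_idx in MIRROR_PAIRS:
                sw = rng.random(F) < noise.swap_prob
                if np.any(sw):
                    tmp = pos[sw, l_idx].copy()
                    pos[sw, l_idx] = pos[sw, r_idx]
                    pos[sw, r_idx] = tmp
                    conf[sw, l_idx] = np.minimum(conf[sw, l_idx], 1)
                    conf[sw, r_idx] = np.minimum(conf[sw, r_idx], 1)
        # out-of-view joints and random dropouts are lost entirely
        lost = dist > sensor.max_range_mm
        axis = sensor.optical_axis
        cos_view = np.sum((-view_dir) * axis[None, None], axis=-1)
        lost |= cos_view < np.cos(np.deg2rad(sensor.hfov_deg / 2.0))
        lost |= rng.random((F, J)) < noise.dropout_prob
        conf[lost] = 0
        pos[lost] = np.nan
        if output_frame == "sensor":
            inv = sensor.pose.inverse()
            keep = ~lost
            pos[keep] = inv.apply(pos[keep])
        out[sensor.sensor_id] = SkeletonTrack(sensor.sensor_id, gt.frame_index.copy(), pos, conf)
    return out


# ---------------------------------------------------------------------------
# benchmark assembly


def default_benchmark(
    seed: int,
    gesture: str = "random_movement",
    n_frames: int = 1000,
    n_sensors: int = 4,
    noise: NoiseModel | None = None,
) -> tuple[dict[str, SkeletonTrack], SkeletonTrack]:
    """Streams + exact ground truth for one seeded benchmark run."""
    params = {"seed": seed} if gesture == "random_movement" else {}
    if gesture == "walking":
        params["mode"] = "in_place"
    spec = GestureSpec(gesture=gesture, n_frames=n_frames, params=params)
    truth = generate_gesture(spec)
    rig = default_rig(n_sensors=n_sensors)
    if noise is None:
        noise = NoiseModel(seed=seed)
    else:
        noise = NoiseModel(**{**asdict(noise), "seed": seed})
    streams = observe(truth, rig, noise)
    return streams, truth


def make_benchmark(
    spec: GestureSpec,
    rig: SensorRig,
    noise: NoiseModel,
    out_dir: str | Path,
    output_frame: str = "global",
) -> dict:
    """Write per-sensor streams, ground truth and a manifest to ``out_dir``.

    Returns the manifest (also saved as ``manifest.json``); re-running with
    the same manifest parameters reproduces the files byte-for-byte.
    """
    from . import io_ as sio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = generate_gesture(spec)
    streams = observe(truth, rig, noise, output_frame=output_frame)
    files = {}
    for sid, track in streams.items():
        path = out_dir / f"stream_{sid}.csv"
        sio.write_stream(track, path)
        files[sid] = path.name
    truth_path = out_dir / "truth.csv"
    sio.write_stream(truth, truth_path)
    manifest = {
        "gesture": spec.gesture,
        "n_frames": spec.n_frames,
        "frame_rate_hz": spec.frame_rate_hz,
        "params": spec.params,
        "segments_mm": spec.segments_mm,
        "noise": asdict(noise),
        "output_frame": output_frame,
        "sensors": [
            {
                "sensor_id": s.sensor_id,
                "rotation": s.pose.rotation.ravel().tolist(),
                "translation_mm": s.pose.translation.tolist(),
                "hfov_deg": s.hfov_deg,
                "max_range_mm": s.max_range_mm,
            }
            for s in rig.sensors
        ],
        "files": {"streams": files, "truth": truth_path.name},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
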