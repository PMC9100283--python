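"""Rigid extrinsic calibration of a multi-sensor rig.

Two stages align every sensor to a user-defined global frame:

1. *sensor-to-sensor*: each sensor observes the centroid of a tracked sphere
   over many synchronized frames; the resulting point-correspondence
   trajectories are registered to the master sensor's trajectory by the
   least-squares (Kabsch/SVD) rigid fit.  Sphere centroids themselves come
   from RANSAC fitting of a known-radius sphere to segmented point clouds.
2. *sensor-to-marker*: a plate with four fiducial centroids defines the
   global frame (origin at marker 1, x along marker2-marker1, z floor to
   ceiling); the master frame is re-expressed in it.

All lengths are millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "CalibrationTrajectory",
    "FitDiagnostics",
    "SphereFitResult",
    "MarkerPlate",
    "ransac_sphere_center",
    "build_trajectories",
    "estimate_rigid_transform",
    "marker_frame",
    "compose",
    "apply",
    "apply_frame",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation; maps points by ``R @ p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Transform one point or an (..., 3) array of points."""
        p = np.asarray(p, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rin = self.rotation.T
        return RigidTransform(Rin, -Rin @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def apply(t: RigidTransform, p: np.ndarray) -> np.ndarray:
    return t.apply(p)


def apply_frame(t: RigidTransform, frame):
    """Transform every observed joint of a :class:`~skelfuse.core.SkeletonFrame`.

    Confidences are untouched; ``none`` joints are passed through.
    """
    from .core import Confidence, JointObservation, SkeletonFrame

    joints = {}
    for name, obs in frame.joints.items():
        if obs.confidence == Confidence.NONE:
            joints[name] = obs
        else:
            joints[name] = JointObservation(t.apply(obs.position), obs.confidence)
    return SkeletonFrame(frame.sensor_id, frame.frame_index, joints)


@dataclass
class CalibrationTrajectory:
    """Index-aligned sphere-centroid correspondences (master vs target)."""

    points_master: np.ndarray
    points_target: np.ndarray

    def __post_init__(self):
        self.points_master = np.asarray(self.points_master, dtype=float)
        self.points_target = np.asarray(self.points_target, dtype=float)
        if self.points_master.shape != self.points_target.shape:
            raise ValueError("master/target correspondence lengths differ")
        if self.points_master.ndim != 2 or self.points_master.shape[1] != 3:
            raise ValueError("trajectories must be (n, 3)")
        if self.n < 3:
            raise ValueError("at least 3 correspondences are required")
        if not (np.all(np.isfinite(self.points_master)) and np.all(np.isfinite(self.points_target))):
            raise ValueError("non-finite trajectory point")

    @property
    def n(self) -> int:
        return self.points_master.shape[0]


@dataclass
class FitDiagnostics:
    """Diagnostics of one Kabsch fit (covariance in mm^2, residual in mm)."""

    covariance: np.ndarray
    singular_values: np.ndarray
    rms_residual: float
    reflection_corrected: bool


@dataclass
class SphereFitResult:
    center: np.ndarray
    inlier_indices: np.ndarray
    iterations_used: int


@dataclass
class MarkerPlate:
    """Four fiducial centroids keyed 0..3; 0, 1, 2 must span a triangle."""

    centroids: dict[int, np.ndarray]
    _area_tol_mm2: float = field(default=1.0, repr=False)

    def __post_init__(self):
        self.centroids = {int(k): np.asarray(v, dtype=float) for k, v in self.centroids.items()}
        for k in (0, 1, 2, 3):
            if k not in self.centroids:
                raise ValueError(f"marker {k} missing")
            if self.centroids[k].shape != (3,):
                raise ValueError("marker centroids must be 3-vectors")
        c0, c1, c2 = (self.centroids[k] for k in (0, 1, 2))
        area = 0.5 * np.linalg.norm(np.cross(c2 - c1, c0 - c1))
        if area <= self._area_tol_mm2:
            raise ValueError("markers 0,1,2 are (near-)collinear")


def _sphere_through_4(p: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Center/radius of the sphere through 4 points, or None if degenerate."""
    # |x - c|^2 = r^2 -> 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2
    A = 2.0 * (p[1:] - p[0])
    b = np.sum(p[1:] ** 2, axis=1) - np.sum(p[0] ** 2)
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    return c, float(np.linalg.norm(p[0] - c))


def _refine_fixed_radius(points: np.ndarray, center: np.ndarray, radius: float,
                         n_iter: int = 20) -> np.ndarray:
    """Gauss-Newton on sum(||p-c|| - radius)^2 with the radius held fixed."""
    c = center.astype(float).copy()
    for _ in range(n_iter):
        d = points - c
        dist = np.linalg.norm(d, axis=1)
        dist = np.maximum(dist, 1e-12)
        r_hat = d / dist[:, None]
        # residual_i = dist_i - radius, d residual / dc = -r_hat
        step, *_ = np.linalg.lstsq(r_hat, dist - radius, rcond=None)
        c = c + step
        if np.linalg.norm(step) < 1e-12:
            break
    return c


def ransac_sphere_center(
    points: np.ndarray,
    radius: float,
    *,
    iterations: int = 200,
    inlier_tol_mm: float = 10.0,
    radius_tol_mm: float = 20.0,
    seed: int = 0,
) -> SphereFitResult:
    """RANSAC center of a sphere of known radius in a segmented point cloud.

    Hypotheses are spheres through random 4-point samples; a hypothesis is
    rejected when its fitted radius differs from ``radius`` by more than
    ``radius_tol_mm``.  The best-consensus center is refined by fixed-radius
    least squares on its inlier set.  Deterministic given ``seed``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = points.shape[0]
    if n < 4:
        raise ValueError("at least 4 points are required for a sphere fit")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_center: np.ndarray | None = None
    for it in range(iterations):
        sample = points[rng.choice(n, size=4, replace=False)]
        fit = _sphere_through_4(sample)
        if fit is None:
            continue
        c, r = fit
        if abs(r - radius) > radius_tol_mm:
            continue
        resid = np.abs(np.linalg.norm(points - c, axis=1) - radius)
        inliers = np.flatnonzero(resid <= inlier_tol_mm)
        if best_inliers is None or len(inliers) > len(best_inliers):
            best_inliers, best_center = inliers, c
    if best_inliers is None or len(best_inliers) < 4:
        raise ValueError("sphere fit failed: no hypothesis with >= 4 inliers")
    center = _refine_fixed_radius(points[best_inliers], best_center, radius)
    resid = np.abs(np.linalg.norm(points - center, axis=1) - radius)
    inliers = np.flatnonzero(resid <= inlier_tol_mm)
    return SphereFitResult(center=center, inlier_indices=inliers, iterations_used=iterations)


def build_trajectories(
    centroid_streams: dict[str, list[tuple[int, np.ndarray | None]]],
    master_id: str,
) -> dict[str, CalibrationTrajectory]:
    """Index-aligned trajectories against the master sensor.

    Only frames in which *every* sensor detected the sphere survive; fewer
    than 3 surviving frames is an error.
    """
    if master_id not in centroid_streams:
        raise ValueError(f"master sensor {master_id!r} not among streams")
    per_sensor: dict[str, dict[int, np.ndarray]] = {}
    for sid, stream in centroid_streams.items():
        d = {}
        for idx, p in stream:
            if p is None:
                continue
            p = np.asarray(p, dtype=float)
            if np.all(np.isfinite(p)):
                d[int(idx)] = p
        per_sensor[sid] = d
    common = set.intersection(*(set(d) for d in per_sensor.values()))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} frames common to all sensors; >= 3 correspondences required"
        )
    order = sorted(common)
    master_pts = np.array([per_sensor[master_id][i] for i in order])
    out = {}
    for sid, d in per_sensor.items():
        if sid == master_id:
            continue
        target = np.array([d[i] for i in order])
        out[sid] = CalibrationTrajectory(points_master=master_pts, points_target=target)
    return out


def estimate_rigid_transform(traj: CalibrationTrajectory) -> tuple[RigidTransform, FitDiagnostics]:
    """Least-squares rigid registration of the target onto the master trajectory.

    Kabsch/SVD: center both sets on their centroids, form the covariance
    ``Cov = sum_i (C_p,i - c_p)(C_M,i - c_M)^T``, decompose ``Cov = U S V^T``
    and take ``R = V diag(1, 1, det(V U^T)) U^T`` (the determinant correction
    excludes reflections), ``T = c_M - R c_p``.
    """
    P = traj.points_target  # sensor p
    M = traj.points_master
    cp = P.mean(axis=0)
    cm = M.mean(axis=0)
    Pc = P - cp
    Mc = M - cm
    cov = Pc.T @ Mc  # maps target-deviations onto master-deviations
    U, S, Vt = np.linalg.svd(cov)
    # rank-deficiency: collinear targets leave the rotation underdetermined
    if traj.n >= 3 and S[0] > 0 and S[1] / S[0] < 1e-9:
        raise ValueError("degenerate (collinear) trajectory geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    corrected = d < 0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cm - R @ cp
    rt = RigidTransform(R, t)
    resid = np.linalg.norm(M - rt.apply(P), axis=1)
    diag = FitDiagnostics(
        covariance=cov,
        singular_values=S,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        reflection_corrected=bool(corrected),
    )
    return rt, diag


def marker_frame(plate: MarkerPlate, up_hint: np.ndarray = (0.0, 0.0, 1.0)) -> RigidTransform:
    """Transform from sensor coordinates into the marker-plate global frame.

    Origin at marker 1; x along marker2 - marker1; z perpendicular to the
    plate with its sign chosen to point floor -> ceiling (``z . up_hint > 0``);
    y completes the right-handed frame (re-orthogonalized as z cross x since
    measured marker vectors need not be perpendicular).
    """
    up_hint = np.asarray(up_hint, dtype=float)
    c0, c1, c2 = (plate.centroids[k] for k in (0, 1, 2))
    x = c2 - c1
    x = x / np.linalg.norm(x)
    y_raw = c0 - c1
    z = np.cross(x, y_raw)
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("marker plate is degenerate (collinear markers)")
    z = z / nz
    if np.dot(z, up_hint) < 0:
        z = -z
    y = np.cross(z, x)
    # rows of R are the new axes: p_global = R (p_sensor - c1)
    R = np.vstack([x, y, z])
    return RigidTransform(R, -R @ c1)
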