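"""Misorientation correction, DBSCAN merging and Kalman tracking."""

import numpy as np
import pytest

from skelfuse.core import Confidence, JointObservation, SkeletonFrame, SkeletonTrack
from skelfuse.fusion import (
    NOISE,
    FusionConfig,
    JointStatus,
    KalmanConfig,
    KalmanJointState,
    arrange_frame,
    check_pair,
    dbscan,
    fuse_frame,
    fuse_sequence,
    kalman_step,
    merge_joint,
    reference_position,
)


def obs(x, y=0.0, z=0.0, conf=Confidence.MEDIUM):
    return JointObservation(np.array([float(x), float(y), float(z)]), conf)


# ---------------------------------------------------------------------------
# reference position


def test_reference_prefers_medium_candidates():
    ref = reference_position([obs(0), obs(10), obs(1000, conf=Confidence.LOW)])
    assert np.allclose(ref, [5, 0, 0])


def test_reference_falls_back_to_low():
    ref = reference_position([obs(0, conf=Confidence.LOW), obs(20, conf=Confidence.LOW)])
    assert np.allclose(ref, [10, 0, 0])


def test_reference_none_when_nothing_tracked():
    assert reference_position([]) is None
    none_obs = JointObservation(np.full(3, np.nan), Confidence.NONE)
    assert reference_position([none_obs, none_obs]) is None


# ---------------------------------------------------------------------------
# pair checking


def test_check_pair_clear_correct_case():
    r = check_pair([100, 0, 0], [-100, 0, 0], [101, 0, 0], [-99, 0, 0])
    assert r.d_correct == pytest.approx(1.0)
    assert r.d_wrong == pytest.approx(199.0)
    assert not r.swapped


def test_check_pair_detects_swap():
    r = check_pair([100, 0, 0], [-100, 0, 0], [-98, 1, 0], [99, -2, 0])
    # oracle: direct distances
    assert r.d_correct == pytest.approx(np.sqrt(198**2 + 1))
    assert r.d_wrong == pytest.approx(np.sqrt(1 + 4))
    assert r.swapped


def test_check_pair_tie_is_not_swapped():
    r = check_pair([100, 0, 0], [-100, 0, 0], [0, 50, 0], [0, 50, 0])
    assert r.d_correct == r.d_wrong
    assert not r.swapped


# ---------------------------------------------------------------------------
# arrangement


def _elbow_frames(rng, swapped_sensors=(), n_sensors=4, sep=300.0, jitter=5.0):
    """Frames with elbows at +/- sep/2 on x; swapped sensors get low confidence."""
    truth_r = np.array([sep / 2, 0.0, 1000.0])
    truth_l = np.array([-sep / 2, 0.0, 1000.0])
    frames = []
    for s in range(n_sensors):
        pr = truth_r + rng.normal(scale=jitter, size=3)
        pl = truth_l + rng.normal(scale=jitter, size=3)
        if s in swapped_sensors:
            pr, pl = pl, pr
            conf = Confidence.LOW
        else:
            conf = Confidence.MEDIUM
        frames.append(
            SkeletonFrame(f"s{s}", 0, {"elbow_R": JointObservation(pr, conf),
                                       "elbow_L": JointObservation(pl, conf)})
        )
    return frames, truth_r, truth_l


def test_arrangement_leaves_clean_frames_untouched():
    rng = np.random.default_rng(0)
    frames, *_ = _elbow_frames(rng)
    out = arrange_frame(frames)
    for a, b in zip(frames, out):
        assert np.allclose(a.joints["elbow_R"].position, b.joints["elbow_R"].position)
        assert np.allclose(a.joints["elbow_L"].position, b.joints["elbow_L"].position)


@pytest.mark.parametrize("swapped", [(1,), (0, 2)])
def test_planted_swaps_corrected(swapped):
    """Oracle: planted truth over 100 seeded frames."""
    ok = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        frames, truth_r, truth_l = _elbow_frames(rng, swapped_sensors=swapped)
        out = arrange_frame(frames)
        good = all(
            np.linalg.norm(f.joints["elbow_R"].position - truth_r) < 50
            and np.linalg.norm(f.joints["elbow_L"].position - truth_l) < 50
            for f in out
        )
        ok += good
    assert ok >= 99


def test_arrangement_is_idempotent():
    rng = np.random.default_rng(5)
    frames, *_ = _elbow_frames(rng, swapped_sensors=(3,))
    once = arrange_frame(frames)
    twice = arrange_frame(once)
    for a, b in zip(once, twice):
        for j in ("elbow_R", "elbow_L"):
            assert np.array_equal(a.joints[j].position, b.joints[j].position)


def test_sensor_missing_one_pair_member_is_skipped():
    frames = [
        SkeletonFrame("a", 0, {"elbow_R": obs(150), "elbow_L": obs(-150)}),
        SkeletonFrame("b", 0, {"elbow_R": obs(151)}),
    ]
    out = arrange_frame(frames)
    assert np.allclose(out[1].joints["elbow_R"].position, [151, 0, 0])
    assert "elbow_L" not in out[1].joints


# ---------------------------------------------------------------------------
# DBSCAN


def _brute_components(pts, eps):
    """Oracle: connected components of the closed eps-proximity graph."""
    n = len(pts)
    adj = np.linalg.norm(pts[:, None] - pts[None], axis=-1) <= eps
    labels = -np.ones(n, dtype=int)
    k = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = k
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if labels[v] < 0:
                    labels[v] = k
                    stack.append(v)
        k += 1
    return labels


def _same_partition(a, b):
    pairs_a = {(i, j) for i in range(len(a)) for j in range(i) if a[i] == a[j]}
    pairs_b = {(i, j) for i in range(len(b)) for j in range(i) if b[i] == b[j]}
    return pairs_a == pairs_b


def test_dbscan_line_example():
    pts = np.array([[0.0, 0, 0], [50, 0, 0], [200, 0, 0]])
    lab = dbscan(pts, eps_mm=100.0, min_neighbors=1)
    assert lab.k == 2
    assert lab.labels[0] == lab.labels[1] != lab.labels[2]


def test_dbscan_single_point_is_one_cluster():
    lab = dbscan(np.zeros((1, 3)), 100.0, 1)
    assert lab.k == 1 and lab.labels[0] == 1


def test_dbscan_closed_inequality_at_exact_eps():
    pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    lab = dbscan(pts, eps_mm=100.0, min_neighbors=1)
    assert lab.k == 1


def test_dbscan_empty_input():
    lab = dbscan(np.empty((0, 3)), 100.0, 1)
    assert lab.k == 0 and len(lab.labels) == 0


def test_dbscan_matches_connectivity_oracle_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = int(rng.integers(1, 51))
        pts = rng.uniform(-500, 500, size=(n, 3))
        eps = float(rng.uniform(10, 600))
        lab = dbscan(pts, eps, 1)
        assert np.all(lab.labels >= 1)  # Nc=1: no noise, partition covers input
        assert _same_partition(lab.labels, _brute_components(pts, eps))


def test_dbscan_matches_sklearn_at_min_neighbors_one():
    from sklearn.cluster import DBSCAN as SkDBSCAN

    rng = np.random.default_rng(7)
    for _ in range(20):
        pts = rng.uniform(-300, 300, size=(40, 3))
        eps = float(rng.uniform(30, 400))
        ours = dbscan(pts, eps, 1).labels
        theirs = SkDBSCAN(eps=eps, min_samples=1).fit(pts).labels_
        assert _same_partition(ours, theirs)


def test_dbscan_noise_with_higher_min_neighbors():
    pts = np.array([[0.0, 0, 0], [10, 0, 0], [15, 0, 0], [500, 0, 0]])
    lab = dbscan(pts, eps_mm=20.0, min_neighbors=3)
    assert lab.labels[3] == NOISE
    assert lab.labels[0] == lab.labels[1] == lab.labels[2] == 1


def test_dbscan_rejects_bad_parameters():
    with pytest.raises(ValueError):
        dbscan(np.zeros((2, 3)), 0.0, 1)
    with pytest.raises(ValueError):
        dbscan(np.zeros((2, 3)), 10.0, 0)


# ---------------------------------------------------------------------------
# joint merging


CFG_A4 = FusionConfig(variant="A4")


def test_merge_coincident_candidates():
    m = merge_joint([np.zeros(3)] * 4, None, None, CFG_A4)
    assert m.status == JointStatus.MERGED
    assert m.n_contributing == 4
    assert np.allclose(m.position, 0)


def test_merge_excludes_far_outlier_and_auxiliary_points():
    cands = [np.array([0.0, 0, 0]), np.array([20.0, 0, 0]), np.array([40.0, 0, 0]),
             np.array([500.0, 500, 500])]
    m = merge_joint(cands, np.array([20.0, 0, 0]), np.array([20.0, 0, 0]), CFG_A4)
    # oracle: chain {0,20,40} is one component, outlier isolated; centroid by hand
    assert m.status == JointStatus.MERGED
    assert m.n_contributing == 3
    assert np.allclose(m.position, [20, 0, 0])


def test_previous_candidate_breaks_two_way_tie():
    a, b = np.array([0.0, 0, 0]), np.array([500.0, 0, 0])
    m = merge_joint([a, b], None, np.array([10.0, 0, 0]), CFG_A4)
    assert m.status == JointStatus.MERGED
    assert m.n_contributing == 1
    assert np.allclose(m.position, a)


def test_merge_without_candidates_uses_previous_or_reports_missing():
    m = merge_joint([], None, np.array([1.0, 2, 3]), CFG_A4)
    assert m.status == JointStatus.PREDICTED
    assert np.allclose(m.position, [1, 2, 3])
    m2 = merge_joint([], None, None, CFG_A4)
    assert m2.status == JointStatus.MISSING


def test_merged_position_inside_hull_of_winning_candidates():
    rng = np.random.default_rng(11)
    for _ in range(100):
        cands = rng.uniform(-300, 300, size=(rng.integers(1, 7), 3))
        ref = rng.uniform(-300, 300, size=3)
        prev = rng.uniform(-300, 300, size=3)
        m = merge_joint(list(cands), ref, prev, CFG_A4)
        if m.status != JointStatus.MERGED:
            continue
        lo, hi = cands.min(axis=0) - 1e-9, cands.max(axis=0) + 1e-9
        assert np.all(m.position >= lo) and np.all(m.position <= hi)


# ---------------------------------------------------------------------------
# Kalman tracking


def test_constant_measurement_is_a_fixed_point():
    cfg = KalmanConfig()
    m = np.array([10.0, -20.0, 30.0])
    st = KalmanJointState()
    for _ in range(200):
        st, tracked = kalman_step(st, m, cfg)
        assert np.allclose(tracked, m, atol=1e-12)
    gain = st.last_gain[0, 0]
    assert gain == pytest.approx(cfg.steady_state_gain, abs=1e-4)


def test_steady_state_gain_matches_riccati_recursion():
    cfg = KalmanConfig(q=0.01, r=1.0)
    # oracle: iterate the scalar predicted-variance recursion to convergence
    M = 1.0 + cfg.q
    for _ in range(10000):
        M = M * cfg.r / (M + cfg.r) + cfg.q
    k_oracle = M / (M + cfg.r)
    closed = (cfg.q + np.sqrt(cfg.q**2 + 4 * cfg.q * cfg.r)) / 2
    assert k_oracle == pytest.approx(closed / (closed + cfg.r), abs=1e-12)
    assert cfg.steady_state_gain == pytest.approx(k_oracle, abs=1e-10)


def test_filter_reduces_white_noise_variance():
    cfg = KalmanConfig()
    for seed in range(10):
        rng = np.random.default_rng(seed)
        z = rng.normal(scale=1.0, size=(2000, 3)) + 5.0
        st = KalmanJointState()
        outs = []
        for m in z:
            st, tracked = kalman_step(st, m, cfg)
            outs.append(tracked)
        outs = np.array(outs[200:])
        assert outs.var(axis=0).mean() < z[200:].var(axis=0).mean()


def test_missing_measurement_propagates_prediction():
    cfg = KalmanConfig()
    st, _ = kalman_step(KalmanJointState(), np.array([1.0, 1, 1]), cfg)
    st2, tracked = kalman_step(st, None, cfg)
    assert np.allclose(tracked, [1, 1, 1])
    assert np.all(np.diag(st2.p_pred) > np.diag(st.p_post))


def test_uninitialized_without_measurement_is_an_error():
    with pytest.raises(ValueError):
        kalman_step(KalmanJointState(), None, KalmanConfig())


def test_covariances_stay_symmetric_psd():
    cfg = KalmanConfig()
    rng = np.random.default_rng(0)
    st = KalmanJointState()
    for i in range(2000):
        z = rng.normal(scale=100, size=3) if rng.random() > 0.3 else None
        if z is None and not st.initialized:
            continue
        st, _ = kalman_step(st, z, cfg)
        for P in (st.p_post, st.p_pred):
            assert np.allclose(P, P.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(P) >= -1e-12)


# ---------------------------------------------------------------------------
# frame / sequence fusion


def _consensus_frames(n_sensors=4, shift=None):
    rng = np.random.default_rng(0)
    base = {name: rng.normal(scale=400, size=3) + [0, 0, 1000] for name in
            ("pelvis", "wrist_R", "ankle_L")}
    frames = []
    for s in range(n_sensors):
        joints = {n: JointObservation(p.copy()) for n, p in base.items()}
        if shift is not None and s == 0:
            joints["wrist_R"] = JointObservation(base["wrist_R"] + shift)
        frames.append(SkeletonFrame(f"s{s}", 0, joints))
    return frames, base


@pytest.mark.parametrize("variant", ["A1", "A3", "A4", "A5"])
def test_consensus_frames_reproduce_input(variant):
    frames, base = _consensus_frames()
    merged, _ = fuse_frame(frames, config=FusionConfig(variant=variant))
    for name, p in base.items():
        assert merged[name].status == JointStatus.MERGED
        assert np.allclose(merged[name].position, p, atol=1e-9)


def test_outlier_shifts_plain_average_but_not_clustered_variants():
    shift = np.array([500.0, 0, 0])
    frames, base = _consensus_frames(shift=shift)
    m1, _ = fuse_frame(frames, config=FusionConfig(variant="A1"))
    assert np.allclose(m1["wrist_R"].position, base["wrist_R"] + shift / 4, atol=1e-9)
    for v in ("A3", "A4", "A5"):
        m, _ = fuse_frame(frames, config=FusionConfig(variant=v))
        assert np.allclose(m["wrist_R"].position, base["wrist_R"], atol=1e-9)
        assert m["wrist_R"].n_contributing == 3


def test_total_dropout_yields_predicted_only_with_previous():
    frames, base = _consensus_frames()
    for f in frames:
        del f.joints["ankle_L"]
    prev = {"ankle_L": np.array([7.0, 8, 9])}
    for v in ("A4", "A5"):
        merged, _ = fuse_frame(frames, prev_merged=prev, config=FusionConfig(variant=v))
        assert merged["ankle_L"].status == JointStatus.PREDICTED
    m3, _ = fuse_frame(frames, prev_merged=prev, config=FusionConfig(variant="A3"))
    assert m3["ankle_L"].status == JointStatus.MISSING


def test_empty_frame_list_is_an_error():
    with pytest.raises(ValueError):
        fuse_frame([])


def _tracks_from_pose(pose, n_frames, n_sensors=4, jitter=0.0, seed=0, drop_frame=None):
    rng = np.random.default_rng(seed)
    tracks = {}
    for s in range(n_sensors):
        pos = np.tile(pose, (n_frames, 1, 1)) + rng.normal(scale=jitter, size=(n_frames, 16, 3))
        conf = np.full((n_frames, 16), 2, dtype=np.int8)
        if drop_frame is not None:
            conf[drop_frame] = 0
            pos[drop_frame] = np.nan
        tracks[f"s{s}"] = SkeletonTrack(f"s{s}", np.arange(n_frames), pos, conf)
    return tracks


def _standing_pose():
    from skelfuse.simulator import GestureSpec, generate_gesture

    spec = GestureSpec("hands_up_down", n_frames=1, params={"amplitude_deg": 0.0})
    return generate_gesture(spec).positions[0]


def test_single_frame_sequence_equals_fuse_frame():
    pose = _standing_pose()
    tracks = _tracks_from_pose(pose, 1, jitter=3.0, seed=4)
    cfg = FusionConfig(variant="A4")
    seq = fuse_sequence(tracks, cfg)
    frames = [t.frame(0) for t in tracks.values()]
    merged, _ = fuse_frame(frames, config=cfg)
    from skelfuse.core import JOINTS

    for j, name in enumerate(JOINTS):
        assert np.allclose(seq.positions[0, j], merged[name].position, atol=1e-9)


def test_sequence_marks_all_sensor_dropout_frame_predicted():
    pose = _standing_pose()
    tracks = _tracks_from_pose(pose, 10, jitter=1.0, seed=1, drop_frame=7)
    seq = fuse_sequence(tracks, FusionConfig(variant="A4"))
    assert np.all(seq.status[7] == JointStatus.PREDICTED)
    assert np.all(seq.status[6] == JointStatus.MERGED)
    assert np.all(seq.status[8] == JointStatus.MERGED)


def test_sustained_dropout_becomes_missing():
    pose = _standing_pose()
    tracks = _tracks_from_pose(pose, 50, jitter=1.0, seed=1)
    for t in tracks.values():
        t.confidence[10:, 0] = 0  # pelvis lost everywhere from frame 10 on
        t.positions[10:, 0] = np.nan
    seq = fuse_sequence(tracks, FusionConfig(variant="A4", max_coast_frames=5))
    assert np.all(seq.status[10:15, 0] == JointStatus.PREDICTED)
    assert np.all(seq.status[16:, 0] == JointStatus.MISSING)


def test_tracking_variance_smaller_than_plain_average_on_constant_pose():
    pose = _standing_pose()
    wins = 0
    for seed in range(10):
        tracks = _tracks_from_pose(pose, 100, jitter=5.0, seed=seed)
        err = {}
        for v in ("A1", "A5"):
            seq = fuse_sequence(tracks, FusionConfig(variant=v))
            err[v] = np.nanvar(seq.positions - pose, axis=0).mean()
        wins += err["A5"] < err["A1"]
    assert wins == 10
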