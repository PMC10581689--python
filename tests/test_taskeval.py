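import math

import numpy as np
import pytest

from hybridarm import (
    HandLocation,
    Tolerance,
    clean_trials,
    movement_times,
    phase_metrics,
    spread_volume,
    success_rate,
    validate_target,
)
from hybridarm.synthmove import (
    SynergyParams,
    generate_session,
    inject_freezing,
    inject_jumping,
)
from hybridarm.taskeval import (
    SynergyOracleModel,
    TrialResult,
    run_closed_loop_phase,
)


def _loc(x=0.35, y=0.0, z=-0.10, incl=0.5, azim=0.0):
    return HandLocation(x, y, z, incl, azim)


# -- target validation --------------------------------------------------------


def test_validate_inside_and_outside():
    tg = _loc()
    assert validate_target(tg, tg, Tolerance.hard())
    # 3 cm positional offset, aligned axis: fails hard (2 cm), passes relaxed (4 cm)
    off = _loc(x=0.35 + 0.03)
    assert not validate_target(off, tg, Tolerance.hard())
    assert validate_target(off, tg, Tolerance.relaxed())
    # aligned position, 7 deg axis error: fails hard (5 deg), passes relaxed (10 deg)
    tilted = _loc(incl=0.5 + math.radians(7))
    assert not validate_target(tilted, tg, Tolerance.hard())
    assert validate_target(tilted, tg, Tolerance.relaxed())


def test_validate_boundary_inclusive():
    # exactly-representable offsets so the boundary comparison is exact
    tg = _loc(x=0.25)
    tol = Tolerance(pos_tol=0.125, ang_tol=0.25, name="custom")
    at_pos_edge = _loc(x=0.25 + 0.125)
    assert validate_target(at_pos_edge, tg, tol)
    at_ang_edge = _loc(x=0.25, incl=0.5 + 0.25 - 1e-12)
    assert validate_target(at_ang_edge, tg, tol)


def test_relaxed_tolerance_is_superset():
    rng = np.random.default_rng(0)
    tg = _loc()
    for _ in range(200):
        hand = _loc(
            x=0.35 + rng.normal(0, 0.02),
            y=rng.normal(0, 0.02),
            z=-0.10 + rng.normal(0, 0.02),
            incl=0.5 + rng.normal(0, 0.1),
            azim=rng.normal(0, 0.1),
        )
        if validate_target(hand, tg, Tolerance.hard()):
            assert validate_target(hand, tg, Tolerance.relaxed())


# -- closed loop ---------------------------------------------------------------


def test_oracle_closed_loop_100_percent(plausible_targets_50, morph):
    oracle = SynergyOracleModel(morph)
    trials = run_closed_loop_phase(
        oracle, plausible_targets_50[:20], morph, Tolerance.relaxed(), seed=0
    )
    assert success_rate(trials) == 100.0
    assert len(movement_times(trials)) == 20
    assert all(0 < mt <= 10.0 for mt in movement_times(trials))


def test_closed_loop_zero_time_limit_times_out(plausible_targets_50, morph):
    oracle = SynergyOracleModel(morph)
    trials = run_closed_loop_phase(
        oracle, plausible_targets_50[:5], morph, Tolerance.relaxed(), time_limit=0.0, seed=0
    )
    assert success_rate(trials) == 0.0
    assert all(t.movement_time is None for t in trials)
    assert all(math.isinf(t.min_pos_err) for t in trials)


def test_closed_loop_returns_session_with_events(plausible_targets_50, morph):
    oracle = SynergyOracleModel(morph)
    trials, session = run_closed_loop_phase(
        oracle,
        plausible_targets_50[:8],
        morph,
        Tolerance.relaxed(),
        seed=0,
        return_session=True,
    )
    assert len(session.trial_slices()) == 8
    shown = [e for e in session.events if e.kind == "target_shown"]
    assert [e.target_index for e in shown] == list(range(8))
    # recorded samples stop at validation: trial length matches movement time
    for t, (_, sl) in zip(trials, session.trial_slices()):
        assert t.success
        assert sl.stop - sl.start == pytest.approx(t.movement_time * session.rate)


def test_closed_loop_deterministic(plausible_targets_50, morph):
    oracle = SynergyOracleModel(morph)
    a = run_closed_loop_phase(oracle, plausible_targets_50[:5], morph, Tolerance.hard(), seed=3)
    b = run_closed_loop_phase(oracle, plausible_targets_50[:5], morph, Tolerance.hard(), seed=3)
    assert a == b


# -- cleaning ------------------------------------------------------------------


def test_clean_session_untouched(small_session):
    cleaned, report = clean_trials(small_session)
    assert report == []
    assert len(cleaned) == len(small_session)
    np.testing.assert_array_equal(cleaned.angles, small_session.angles)


def test_clean_removes_injected_freezing_exactly(small_session):
    frozen = inject_freezing(small_session, trial_index=7, duration=0.6)
    cleaned, report = clean_trials(frozen)
    assert report == [{"trial": 7, "reason": "freezing"}]
    _, sl = frozen.trial_slices()[7]
    assert len(cleaned) == len(frozen) - (sl.stop - sl.start)
    assert all(e.target_index != 7 for e in cleaned.events)


def test_clean_removes_injected_jumping_exactly(small_session):
    jumped = inject_jumping(small_session, trial_index=11, magnitude=0.02)
    cleaned, report = clean_trials(jumped)
    assert report == [{"trial": 11, "reason": "jumping"}]
    _, sl = jumped.trial_slices()[11]
    assert len(cleaned) == len(jumped) - (sl.stop - sl.start)


def test_clean_removes_both_kinds(small_session):
    bad = inject_jumping(inject_freezing(small_session, 2, 0.6), 9, 0.02)
    cleaned, report = clean_trials(bad)
    assert sorted(r["trial"] for r in report) == [2, 9]
    reasons = {r["trial"]: r["reason"] for r in report}
    assert reasons == {2: "freezing", 9: "jumping"}


def test_sub_threshold_artifacts_survive(small_session):
    # 0.3 s of stillness (< 0.5 s) and a 0.005 m step (< 0.01 m) are tolerated
    mild = inject_freezing(small_session, trial_index=4, duration=0.3)
    mild = inject_jumping(mild, trial_index=5, magnitude=0.005)
    _, report = clean_trials(mild)
    assert report == []


# -- metrics -------------------------------------------------------------------


def _trial(i, success, mt=None):
    return TrialResult(
        target_index=i,
        success=success,
        movement_time=mt,
        min_pos_err=0.0 if success else 0.1,
        min_ang_err=0.0 if success else 0.3,
    )


def test_success_rate_and_movement_times():
    trials = [_trial(0, True, 1.0), _trial(1, False), _trial(2, True, 2.0), _trial(3, True, 3.0)]
    assert success_rate(trials) == 75.0
    assert movement_times(trials) == [1.0, 2.0, 3.0]
    with pytest.raises(ValueError):
        success_rate([])


def test_trial_result_consistency():
    with pytest.raises(ValueError, match="movement_time"):
        TrialResult(0, True, None, 0.0, 0.0)
    with pytest.raises(ValueError, match="movement_time"):
        TrialResult(0, False, 1.0, 0.0, 0.0)


def test_phase_metrics_summary():
    trials = [_trial(0, True, 1.0), _trial(1, True, 3.0)]
    pts = np.random.default_rng(0).normal(0, 0.01, (200, 3))
    m = phase_metrics(trials, pts, n_trials_removed=1)
    assert m.success_rate == 100.0
    assert m.median_mt == 2.0
    assert m.spread_volume > 0
    assert m.n_trials_kept == 2 and m.n_trials_removed == 1


# -- spread volume --------------------------------------------------------------


def _brute_force_mvee(points, tol=1e-4, max_iter=2_000_000):
    """Independent Khachiyan implementation used as an oracle (volume in m^3).

    Stops on the duality gap max_j m_j <= (1 + tol)(d + 1), which bounds the
    relative volume error by roughly (d/2) * tol.
    """
    p = np.asarray(points, dtype=float)
    n, d = p.shape
    q = np.vstack([p.T, np.ones(n)])
    u = np.ones(n) / n
    for _ in range(max_iter):
        v = (q * u) @ q.T
        m = np.einsum("ij,ij->j", q, np.linalg.solve(v, q))
        j = int(np.argmax(m))
        if m[j] <= (1.0 + tol) * (d + 1.0):
            break
        step = (m[j] - d - 1.0) / ((d + 1) * (m[j] - 1.0))
        u *= 1 - step
        u[j] += step
    else:
        raise RuntimeError("oracle MVEE did not converge")
    c = p.T @ u
    a = np.linalg.inv((p.T * u) @ p - np.outer(c, c)) / d
    return (4.0 / 3.0) * math.pi / math.sqrt(np.linalg.det(a))


def test_spread_volume_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    pts = rng.normal(0.0, 0.05, (10_000, 3))
    got = spread_volume(pts, coverage=0.9)

    # oracle: same trim rule, brute-force MVEE on the kept points
    x = pts - pts.mean(axis=0)
    cov = (x.T @ x) / pts.shape[0]
    d2 = np.einsum("ij,ij->i", x @ np.linalg.inv(cov), x)
    kept = pts[np.argsort(d2)[: int(round(0.9 * pts.shape[0]))]]
    from scipy.spatial import ConvexHull

    kept = kept[ConvexHull(kept).vertices]
    want = _brute_force_mvee(kept) * 1000.0
    assert got == pytest.approx(want, rel=0.05)


def test_spread_volume_rigid_motion_invariance():
    rng = np.random.default_rng(1)
    pts = rng.normal(0.0, 0.03, (2000, 3)) * np.array([1.0, 0.5, 0.25])
    base = spread_volume(pts)
    # rotation about an arbitrary axis + translation
    from scipy.spatial.transform import Rotation

    r = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = pts @ r.T + np.array([0.5, -0.2, 1.0])
    assert spread_volume(moved) == pytest.approx(base, rel=0.01)


def test_spread_volume_scales_cubically():
    rng = np.random.default_rng(2)
    pts = rng.normal(0.0, 0.02, (3000, 3))
    base = spread_volume(pts)
    assert spread_volume(2.0 * pts) == pytest.approx(8.0 * base, rel=0.01)


def test_spread_volume_degenerate_cloud_is_zero():
    pts = np.zeros((100, 3))
    with pytest.warns(UserWarning, match="degenerate"):
        assert spread_volume(pts) == 0.0
    plane = np.random.default_rng(3).normal(0, 0.05, (100, 3))
    plane[:, 2] = 0.0
    with pytest.warns(UserWarning, match="degenerate"):
        assert spread_volume(plane) == 0.0


def test_spread_volume_validation():
    with pytest.raises(ValueError):
        spread_volume(np.zeros((5, 3)))
    with pytest.raises(ValueError):
        spread_volume(np.zeros((100, 2)))
    with pytest.raises(ValueError):
        spread_volume(np.random.default_rng(0).normal(0, 1, (100, 3)), coverage=1.5)


def test_spread_volume_known_ellipsoid():
    """Points on an axis-aligned ellipsoid surface: MVEE volume = 4/3 pi abc."""
    rng = np.random.default_rng(4)
    u = rng.normal(size=(5000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    abc = np.array([0.06, 0.04, 0.02])
    pts = u * abc
    got = spread_volume(pts, coverage=1.0)
    want = (4.0 / 3.0) * math.pi * np.prod(abc) * 1000.0
    assert got == pytest.approx(want, rel=0.02)
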