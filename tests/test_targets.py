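import math

import numpy as np
import pytest

from hybridarm import (
    ArmMorphology,
    HandLocation,
    RangeOfMotion,
    Target,
    downsample,
    estimate_rom,
    filter_target,
    possible_targets,
    sample_plausible_targets,
)
from hybridarm.cli import default_rom_bounds
from hybridarm.gng import GngParams, GrowingNeuralGas, gng_fit
from hybridarm.kinematics import ANGLE_NAMES, hand_locations_batch
from hybridarm.synthmove import Session, SynergyParams, generate_rom_sweep_session
from hybridarm.targets import ELBOW_EXTENSION_CAP, filter_locations

E_FE = ANGLE_NAMES.index("e_fe")


# -- ROM estimation -------------------------------------------------------


def test_rom_recovers_sweep_bounds(morph):
    bounds = default_rom_bounds()
    sweep = generate_rom_sweep_session(
        bounds, morph, SynergyParams(noise_sd=0.0, shoulder_jitter_sd=0.0), seed=0
    )
    rom = estimate_rom(sweep, cap_elbow=False)
    np.testing.assert_allclose(rom.bounds, bounds, atol=1e-12)


def test_elbow_extension_cap_arithmetic(morph):
    """A 10-150 deg observed elbow excursion is capped at 31 deg extension."""
    bounds = default_rom_bounds()
    bounds[E_FE] = np.radians([10.0, 150.0])
    sweep = generate_rom_sweep_session(
        bounds, morph, SynergyParams(noise_sd=0.0, shoulder_jitter_sd=0.0), seed=0
    )
    rom = estimate_rom(sweep)
    assert ELBOW_EXTENSION_CAP == 0.85
    assert np.degrees(rom.bounds[E_FE, 0]) == pytest.approx(31.0, abs=1e-9)
    assert np.degrees(rom.bounds[E_FE, 1]) == pytest.approx(150.0, abs=1e-9)
    # all other DoFs untouched
    mask = np.ones(7, dtype=bool)
    mask[E_FE] = False
    np.testing.assert_allclose(rom.bounds[mask], bounds[mask], atol=1e-12)


def test_rom_constant_dof_raises(morph):
    n = 100
    angles = np.random.default_rng(0).normal(0, 0.2, (n, 7))
    angles[:, 2] = 0.5  # h_r never moves
    ses = Session(t=np.arange(n) / 90.0, angles=angles, shoulder_pos=np.zeros((n, 3)))
    with pytest.raises(ValueError, match="h_r"):
        estimate_rom(ses)


def test_rom_empty_session_raises():
    ses = Session(t=np.empty(0), angles=np.empty((0, 7)), shoulder_pos=np.empty((0, 3)))
    with pytest.raises(ValueError, match="empty"):
        estimate_rom(ses)


def test_rom_shape_validation():
    with pytest.raises(ValueError):
        RangeOfMotion(np.zeros((3, 2)))
    with pytest.raises(ValueError, match="min < max"):
        RangeOfMotion(np.tile([0.5, 0.5], (7, 1)))


# -- workspace filters ----------------------------------------------------


def test_filter_hand_checked_cases(morph):
    al = morph.arm_length  # 0.63 m
    good = HandLocation(0.30, 0.0, -0.10, math.radians(30), 0.0)
    assert filter_target(good, morph)
    # axis more than 80 deg from vertical
    assert not filter_target(HandLocation(0.30, 0.0, -0.10, math.radians(81), 0.0), morph)
    # not in front of the frontal plane by arm_length/3
    assert not filter_target(HandLocation(al / 3 - 1e-6, 0.0, -0.10, 0.3, 0.0), morph)
    # lower than 2/3 arm length below the shoulder
    assert not filter_target(HandLocation(0.30, 0.0, -(2 * al / 3 + 1e-6), 0.3, 0.0), morph)
    # boundary: exactly at the depth limit is allowed, frontal boundary is not
    assert filter_target(HandLocation(0.30, 0.0, -2 * al / 3, 0.3, 0.0), morph)
    assert not filter_target(HandLocation(al / 3, 0.0, -0.10, 0.3, 0.0), morph)


def test_plausible_targets_count_roles_and_filters(rom, morph):
    targets = sample_plausible_targets(rom, morph, n=51, seed=5)
    assert len(targets) == 51
    assert [t.index for t in targets] == list(range(51))
    assert all(t.role == ("pick" if i % 2 == 0 else "place") for i, t in enumerate(targets))
    locs = np.array([t.location.to_array() for t in targets])
    assert filter_locations(locs, morph).all()


def test_plausible_targets_deterministic(rom, morph):
    a = sample_plausible_targets(rom, morph, n=20, seed=8)
    b = sample_plausible_targets(rom, morph, n=20, seed=8)
    assert a == b
    c = sample_plausible_targets(rom, morph, n=20, seed=9)
    assert a != c


def test_plausible_targets_budget_exhaustion(morph):
    # a ROM pinned to hanging-arm postures never passes the frontal filter
    bounds = np.tile([-1e-3, 1e-3], (7, 1))
    rom = RangeOfMotion(bounds)
    with pytest.raises(RuntimeError, match="draws"):
        sample_plausible_targets(rom, morph, n=5, seed=0, max_draw_factor=10)


def test_target_role_validation():
    loc = HandLocation(0.3, 0.0, -0.1, 0.3, 0.0)
    with pytest.raises(ValueError, match="role"):
        Target(location=loc, role="fetch", index=0)


# -- downsampling ---------------------------------------------------------


def test_downsample(small_session):
    ds = downsample(small_session, 10)
    assert len(ds) == math.ceil(len(small_session) / 10)
    np.testing.assert_array_equal(ds.angles, small_session.angles[::10])
    assert ds.rate == pytest.approx(small_session.rate / 10)
    assert downsample(small_session, 1) is small_session
    with pytest.raises(ValueError):
        downsample(small_session, 0)


# -- growing neural gas ---------------------------------------------------


def _two_cluster_data(seed=0, n=400, sd=0.05):
    rng = np.random.default_rng(seed)
    c1 = np.full(7, -1.0)
    c2 = np.full(7, 1.0)
    pts = np.vstack(
        [c1 + rng.normal(0, sd, (n // 2, 7)), c2 + rng.normal(0, sd, (n // 2, 7))]
    )
    return pts, np.vstack([c1, c2])


def test_gng_two_clusters_match_kmeans_oracle():
    pytest.importorskip("sklearn")
    from sklearn.cluster import KMeans

    data, _ = _two_cluster_data()
    nodes = gng_fit(data, GngParams(n_nodes=2, seed=0))
    assert nodes.shape == (2, 7)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(data)
    centers = km.cluster_centers_
    # match each node to its nearest k-means centroid, within cluster radius
    radius = 0.05 * math.sqrt(7) * 4
    d = np.linalg.norm(nodes[:, None, :] - centers[None, :, :], axis=2)
    assert set(np.argmin(d, axis=1)) == {0, 1}
    assert d.min(axis=1).max() < radius


def test_gng_exact_node_budget(small_session):
    postures = downsample(small_session, 10).angles
    for budget in (50, 120):
        nodes = gng_fit(postures, GngParams(n_nodes=budget, seed=0))
        assert nodes.shape == (budget, 7)


def test_gng_nodes_inside_data_bounding_box(small_session):
    postures = downsample(small_session, 10).angles
    nodes = gng_fit(postures, GngParams(n_nodes=80, seed=0))
    lo, hi = postures.min(axis=0), postures.max(axis=0)
    assert np.all(nodes >= lo - 1e-12) and np.all(nodes <= hi + 1e-12)


def test_gng_quantization_error_non_increasing(small_session):
    postures = downsample(small_session, 10).angles
    errs = []
    for budget in (10, 40, 160):
        g = GrowingNeuralGas(GngParams(n_nodes=budget, seed=0))
        g.fit(postures)
        errs.append(g.quantization_error(postures))
    assert errs[0] >= errs[1] >= errs[2]


def test_gng_deterministic(small_session):
    postures = downsample(small_session, 10).angles
    a = gng_fit(postures, GngParams(n_nodes=30, seed=4))
    b = gng_fit(postures, GngParams(n_nodes=30, seed=4))
    np.testing.assert_array_equal(a, b)


def test_gng_unachievable_budget_raises():
    data = np.random.default_rng(0).normal(0, 1, (50, 7))
    with pytest.raises(ValueError, match="cannot grow"):
        gng_fit(data, GngParams(n_nodes=200, lambda_insert=100, max_passes=2))


def test_gng_param_validation():
    with pytest.raises(ValueError):
        GngParams(n_nodes=1)
    with pytest.raises(ValueError):
        GngParams(eps_b=1.5)


# -- possible targets -----------------------------------------------------


def test_possible_targets_count_and_separation(small_session, morph):
    postures = downsample(small_session, 10).angles
    nodes = gng_fit(postures, GngParams(n_nodes=60, seed=0))
    targets = possible_targets(nodes, morph, seed=0)
    assert len(targets) == 60
    centers = np.array([t.location.center for t in targets])
    gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    assert gaps.min() >= 0.20
    assert all(t.role == ("pick" if i % 2 == 0 else "place") for i, t in enumerate(targets))
    # the target set is exactly the FK image of the nodes (as a set)
    locs = hand_locations_batch(nodes, morph)
    got = np.array(sorted(map(tuple, np.round(centers, 9))))
    want = np.array(sorted(map(tuple, np.round(locs[:, :3], 9))))
    np.testing.assert_array_equal(got, want)


def test_possible_targets_infeasible_separation_raises(morph):
    # two nearly identical postures can never be 20 cm apart
    nodes = np.tile(np.array([0.3, 0.2, 0.0, 1.2, 0.0, 0.0, 0.0]), (3, 1))
    with pytest.raises(RuntimeError, match="separation"):
        possible_targets(nodes, morph, seed=0, max_retries=5)


def test_possible_targets_deterministic(small_session, morph):
    postures = downsample(small_session, 10).angles
    nodes = gng_fit(postures, GngParams(n_nodes=40, seed=0))
    a = possible_targets(nodes, morph, seed=3)
    b = possible_targets(nodes, morph, seed=3)
    assert a == b
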