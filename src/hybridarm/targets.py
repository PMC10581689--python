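"""Target-set generation.

Two target sets drive the pick-and-place pipeline:

* *Plausible* targets: 7-DoF postures drawn uniformly within the subject's
  per-joint ranges of motion, pushed through forward kinematics, and kept only
  if they satisfy three workspace filters - the hand axis within 80 deg of
  vertical (no downward- or horizontally-pointing targets), the centre more
  than a third of the arm length in front of the frontal plane, and no more
  than two thirds of the arm length below the shoulder's horizontal plane.
  Drawing continues until the requested count is reached.

* *Possible* targets: the forward-kinematic image of Growing-Neural-Gas nodes
  fitted to postures the subject actually produced, hence guaranteed reachable
  with natural coordination. Joint limits are anatomically interdependent, so
  uniform ROM draws can combine extreme excursions into uncomfortable or
  impossible postures; the GNG step avoids exactly that.

Both sets are ordered into alternating pick/place sequences; possible-target
sequences additionally forbid consecutive centres closer than 20 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gng import GngParams, gng_fit  # noqa: F401  (re-exported for convenience)
from .kinematics import (
    ANGLE_NAMES,
    ArmMorphology,
    HandLocation,
    hand_locations_batch,
)
from .synthmove import Session

__all__ = [
    "RangeOfMotion",
    "Target",
    "GngParams",
    "estimate_rom",
    "filter_target",
    "filter_locations",
    "sample_plausible_targets",
    "gng_fit",
    "possible_targets",
    "downsample",
    "ELBOW_EXTENSION_CAP",
    "MIN_CONSECUTIVE_SEPARATION",
]

#: fraction of the observed elbow excursion kept away from full extension,
#: so the shoulder-elbow-wrist triangle used for humeral rotation never vanishes
ELBOW_EXTENSION_CAP = 0.85

#: minimum distance between the centres of consecutive targets in a sequence
MIN_CONSECUTIVE_SEPARATION = 0.20

_E_FE_IDX = ANGLE_NAMES.index("e_fe")


@dataclass(frozen=True)
class RangeOfMotion:
    """Per-DoF (min, max) bounds in radians, shape (n_dofs, 2).

    Seven DoFs for a full arm; two (shoulder only) in residual-limb mode.
    """

    bounds: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] not in (2, 7):
            raise ValueError(f"bounds must be (7, 2) or (2, 2), got {b.shape}")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("each DoF must have min < max (zero-width ROM is degenerate)")
        object.__setattr__(self, "bounds", b)

    @property
    def n_dofs(self) -> int:
        return self.bounds.shape[0]

    def clip(self, angles: np.ndarray) -> np.ndarray:
        return np.clip(angles, self.bounds[:, 0], self.bounds[:, 1])


@dataclass(frozen=True)
class Target:
    """A pick or place location in a task sequence."""

    location: HandLocation
    role: str  # pick | place
    index: int

    def __post_init__(self) -> None:
        if self.role not in ("pick", "place"):
            raise ValueError(f"role must be 'pick' or 'place', got {self.role!r}")


def estimate_rom(session: Session, cap_elbow: bool = True) -> RangeOfMotion:
    """Per-DoF ranges of motion from the extreme angles reached in a session.

    The session should contain elementary movements sweeping each DoF across
    its range. The extension end of the elbow range is pulled in by
    ``1 - ELBOW_EXTENSION_CAP`` of the observed excursion, avoiding postures
    where the arm is straight enough for the humeral-rotation triangle to
    degenerate.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    q = session.angles
    lo = q.min(axis=0)
    hi = q.max(axis=0)
    if np.any(hi - lo < 1e-12):
        flat = [ANGLE_NAMES[i] for i in range(len(lo)) if hi[i] - lo[i] < 1e-12]
        raise ValueError(f"degenerate (constant) trajectory for DoF(s): {', '.join(flat)}")
    bounds = np.column_stack([lo, hi])
    if cap_elbow and bounds.shape[0] == 7:
        excursion = hi[_E_FE_IDX] - lo[_E_FE_IDX]
        bounds[_E_FE_IDX, 0] = lo[_E_FE_IDX] + (1.0 - ELBOW_EXTENSION_CAP) * excursion
    return RangeOfMotion(bounds)


def filter_locations(locations: np.ndarray, morph: ArmMorphology) -> np.ndarray:
    """Vectorised workspace filter; (n, 5) locations -> (n,) boolean mask.

    Criteria: hand axis within 80 deg of vertical; centre strictly more than
    arm_length/3 anterior (+x) of the frontal plane; centre at most
    2*arm_length/3 below the shoulder's horizontal plane.
    """
    loc = np.atleast_2d(np.asarray(locations, dtype=float))
    al = morph.arm_length
    ok_axis = loc[:, 3] <= math.radians(80.0)
    ok_front = loc[:, 0] > al / 3.0
    ok_depth = -loc[:, 2] <= 2.0 * al / 3.0
    return ok_axis & ok_front & ok_depth


def filter_target(loc: HandLocation, morph: ArmMorphology) -> bool:
    """True iff a hand location passes the three workspace criteria."""
    return bool(filter_locations(loc.to_array()[None, :], morph)[0])


def _assign_roles(locations: list[HandLocation]) -> list[Target]:
    """Alternate pick/place roles along an already-ordered sequence."""
    return [
        Target(location=loc, role="pick" if i % 2 == 0 else "place", index=i)
        for i, loc in enumerate(locations)
    ]


def sample_plausible_targets(
    rom: RangeOfMotion,
    morph: ArmMorphology,
    n: int = 300,
    seed: int = 0,
    max_draw_factor: int = 10_000,
) -> list[Target]:
    """Rejection-sample ``n`` workspace-filtered targets from uniform ROM draws.

    Postures are drawn from a multivariate uniform distribution over the ROM,
    mapped to hand locations by forward kinematics, and kept if they pass
    :func:`filter_target`; drawing continues until ``n`` suitable targets are
    obtained (or ``max_draw_factor * n`` draws are exhausted). The accepted
    targets are then shuffled, half treated as picking and half as placing
    locations, alternating along the sequence.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if rom.n_dofs != 7:
        raise ValueError("plausible-target sampling needs a full 7-DoF ROM")
    rng = np.random.default_rng(seed)
    lo = rom.bounds[:, 0]
    hi = rom.bounds[:, 1]
    kept: list[np.ndarray] = []
    drawn = 0
    budget = max_draw_factor * n
    batch = max(4 * n, 256)
    while len(kept) < n:
        if drawn >= budget:
            raise RuntimeError(
                f"exceeded {budget} draws with only {len(kept)}/{n} targets accepted; "
                "the workspace filters reject (almost) everything for this ROM/morphology"
            )
        m = min(batch, budget - drawn)
        q = rng.uniform(lo, hi, size=(m, 7))
        drawn += m
        locs = hand_locations_batch(q, morph)
        good = locs[filter_locations(locs, morph)]
        kept.extend(good)
    kept = kept[:n]
    order = rng.permutation(n)
    locations = [HandLocation.from_array(kept[i]) for i in order]
    return _assign_roles(locations)


def possible_targets(
    nodes: np.ndarray,
    morph: ArmMorphology,
    seed: int = 0,
    min_separation: float = MIN_CONSECUTIVE_SEPARATION,
    max_retries: int = 1000,
) -> list[Target]:
    """Forward-kinematic image of GNG nodes, ordered into a task sequence.

    Targets are drawn at random without replacement into a sequence whose
    consecutive centres are at least ``min_separation`` apart, with roles
    alternating pick/place. Raises if no valid ordering is found within
    ``max_retries`` attempts.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[0] < 1:
        raise ValueError("need a non-empty (n, 7) node array")
    locs = hand_locations_batch(nodes, morph)
    centers = locs[:, :3]
    n = locs.shape[0]
    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        remaining = list(rng.permutation(n))
        seq = [remaining.pop()]
        ok = True
        while remaining:
            prev = centers[seq[-1]]
            dists = np.linalg.norm(centers[remaining] - prev, axis=1)
            feasible = np.nonzero(dists >= min_separation)[0]
            if feasible.size == 0:
                ok = False
                break
            pick = int(feasible[rng.integers(feasible.size)])
            seq.append(remaining.pop(pick))
        if ok:
            locations = [HandLocation.from_array(locs[i]) for i in seq]
            return _assign_roles(locations)
    raise RuntimeError(
        f"no ordering with consecutive separation >= {min_separation} m found "
        f"after {max_retries} attempts"
    )


def downsample(session: Session, factor: int) -> Session:
    """Keep every ``factor``-th sample of a session (events untouched)."""
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor == 1:
        return session
    return Session(
        t=session.t[::factor],
        angles=session.angles[::factor],
        shoulder_pos=session.shoulder_pos[::factor],
        events=list(session.events),
        morph=session.morph,
        rate=session.rate / factor,
    )
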