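"""Closed-loop pick-and-place evaluation.

A trial is one reach: a target appears, the operator moves, and the trial
succeeds at the first sample where the hybrid hand is inside the target zone -
a region of the 5-D hand-location space bounded by a positional and an angular
tolerance (hard: 2 cm / 5 deg, relaxed: 4 cm / 10 deg) - or times out.
Movement time runs from target appearance to validation. A simulated operator
has no button-press latency, so validation fires at the first in-zone sample.

Data cleaning mirrors motion-capture practice: trials where a monitored
position stays still for at least 0.5 s ("freezing", a tracker dropout) or
where the shoulder moves more than 0.01 m between consecutive samples
("jumping", a tracking glitch) are removed before metrics are computed.

Phase metrics: success rate (percent of validated trials), movement time
(successful trials only), and the shoulder spread volume - the volume of the
minimum-volume ellipsoid enclosing the 90% of shoulder positions closest to
the centroid in Mahalanobis distance, in cubic decimetres, a proxy for trunk
and shoulder compensation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import (
    ArmMorphology,
    HandLocation,
    forward_kinematics_batch,
)
from .synthmove import (
    REST_ANGLES,
    Session,
    SessionEvent,
    SynergyParams,
    min_jerk_trajectory,
    mirror_angles,
    synergy_ik,
)

__all__ = [
    "Tolerance",
    "TrialResult",
    "PhaseMetrics",
    "validate_target",
    "SynergyOracleModel",
    "run_closed_loop_phase",
    "clean_trials",
    "success_rate",
    "movement_times",
    "spread_volume",
    "phase_metrics",
    "FREEZE_DURATION",
    "JUMP_THRESHOLD",
    "STILL_TOL",
]

FREEZE_DURATION = 0.5  # s of stillness that invalidates a trial
JUMP_THRESHOLD = 0.01  # m per sample of shoulder motion that invalidates a trial
STILL_TOL = 1e-6  # m; displacement below this counts as "still"


@dataclass(frozen=True)
class Tolerance:
    """Target-zone bounds: positional (m) and angular (rad) tolerance."""

    pos_tol: float
    ang_tol: float
    name: str = "custom"

    @classmethod
    def hard(cls) -> "Tolerance":
        return cls(0.02, math.radians(5.0), "hard")

    @classmethod
    def relaxed(cls) -> "Tolerance":
        return cls(0.04, math.radians(10.0), "relaxed")


@dataclass(frozen=True)
class TrialResult:
    target_index: int
    success: bool
    movement_time: float | None
    min_pos_err: float
    min_ang_err: float

    def __post_init__(self) -> None:
        if self.success != (self.movement_time is not None):
            raise ValueError("movement_time must be present iff the trial succeeded")


@dataclass(frozen=True)
class PhaseMetrics:
    success_rate: float  # percent
    median_mt: float | None  # s, None if no successful trial
    spread_volume: float  # dm^3
    n_trials_kept: int
    n_trials_removed: int = 0


def validate_target(hand: HandLocation, target, tol: Tolerance) -> bool:
    """True iff the hand is inside the target zone under ``tol``."""
    loc = target.location if hasattr(target, "location") else target
    pos_err = float(np.linalg.norm(hand.center - loc.center))
    ang_err = float(np.arccos(np.clip(np.dot(hand.axis, loc.axis), -1.0, 1.0)))
    return pos_err <= tol.pos_tol and ang_err <= tol.ang_tol


class SynergyOracleModel:
    """Perfect distal-joint predictor given by the generating synergy itself.

    Useful as the ground-truth controller in closed-loop tests: when the
    operator's proximal angles reach the synergy posture for the target, the
    hybrid hand lands exactly on it.
    """

    def __init__(self, morph: ArmMorphology, params: SynergyParams | None = None):
        self.morph = morph
        self.params = params or SynergyParams()
        self._cache: dict[tuple, np.ndarray] = {}

    def predict_distal(self, s_fe: float, s_aa: float, target: HandLocation) -> np.ndarray:
        key = tuple(np.round(target.to_array(), 12))
        if key not in self._cache:
            self._cache[key] = synergy_ik(target, self.morph, self.params).distal
        return self._cache[key]

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], 5))
        for i, row in enumerate(x):
            out[i] = self.predict_distal(row[0], row[1], HandLocation.from_array(row[2:]))
        return out


def run_closed_loop_phase(
    model,
    targets,
    morph: ArmMorphology,
    tol: Tolerance,
    time_limit: float = 10.0,
    operator_params: SynergyParams | None = None,
    seed: int = 0,
    return_session: bool = False,
):
    """Simulate one test phase of the pick-and-place task.

    The simulated operator moves naturally (synergy posture + minimum-jerk)
    toward each target and holds there; at every sample only its two proximal
    angles reach the hybrid arm, whose five distal angles come from ``model``
    queried with the *target* location (run-time goal context, in contrast to
    the hand-location context used at training time). The trial succeeds at the
    first sample whose hybrid hand location is inside the target zone.

    Returns the list of :class:`TrialResult`; with ``return_session=True``,
    also the hybrid-arm session (with trial events) for cleaning and
    spread-volume analysis.
    """
    params = operator_params or SynergyParams()
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.rate
    n_limit = int(round(time_limit * params.rate))

    current = REST_ANGLES if morph.side == "right" else mirror_angles(REST_ANGLES)
    results: list[TrialResult] = []
    chunks: list[np.ndarray] = []
    shoulder_chunks: list[np.ndarray] = []
    events: list[SessionEvent] = []
    n_total = 0

    for i, tg in enumerate(targets):
        loc = tg.location if hasattr(tg, "location") else tg
        if n_limit == 0:
            # no time at all: the trial times out before a single sample
            results.append(
                TrialResult(
                    target_index=i,
                    success=False,
                    movement_time=None,
                    min_pos_err=math.inf,
                    min_ang_err=math.inf,
                )
            )
            events.append(SessionEvent(t=n_total * dt, kind="target_shown", target_index=i))
            events.append(SessionEvent(t=n_total * dt, kind="timeout", target_index=i))
            continue
        goal = synergy_ik(loc, morph, params)
        traj = min_jerk_trajectory(current, goal, params.move_duration, params.rate)
        if traj.shape[0] < n_limit:
            hold = np.tile(traj[-1], (n_limit - traj.shape[0], 1))
            traj = np.vstack([traj, hold])
        else:
            traj = traj[:n_limit]
        prox = traj[:, :2].copy()
        if params.noise_sd > 0:
            prox += rng.normal(0.0, params.noise_sd, prox.shape)

        x = np.column_stack(
            [prox, np.tile(loc.to_array(), (prox.shape[0], 1))]
        )
        distal = model.predict_batch(x)
        hybrid = np.column_stack([prox, distal])
        _, _, center, axis = forward_kinematics_batch(hybrid, morph)
        pos_err = np.linalg.norm(center - loc.center, axis=1)
        ang_err = np.arccos(np.clip(axis @ loc.axis, -1.0, 1.0))
        in_zone = (pos_err <= tol.pos_tol) & (ang_err <= tol.ang_tol)
        hits = np.nonzero(in_zone)[0]

        if hits.size > 0:
            k = int(hits[0])
            mt = (k + 1) * dt
            results.append(
                TrialResult(
                    target_index=i,
                    success=True,
                    movement_time=mt,
                    min_pos_err=float(pos_err[: k + 1].min()),
                    min_ang_err=float(ang_err[: k + 1].min()),
                )
            )
            recorded = hybrid[: k + 1]
        else:
            results.append(
                TrialResult(
                    target_index=i,
                    success=False,
                    movement_time=None,
                    min_pos_err=float(pos_err.min()),
                    min_ang_err=float(ang_err.min()),
                )
            )
            recorded = hybrid

        events.append(SessionEvent(t=n_total * dt, kind="target_shown", target_index=i))
        n_total += recorded.shape[0]
        events.append(
            SessionEvent(
                t=(n_total - 1) * dt,
                kind="validated" if hits.size > 0 else "timeout",
                target_index=i,
            )
        )
        chunks.append(recorded)
        shoulder_chunks.append(
            rng.normal(0.0, params.shoulder_jitter_sd, (recorded.shape[0], 3))
        )
        current = goal

    if not return_session:
        return results
    if not chunks:
        empty = Session(
            t=np.empty(0),
            angles=np.empty((0, 7)),
            shoulder_pos=np.empty((0, 3)),
            events=events,
            morph=morph,
            rate=params.rate,
        )
        return results, empty
    angles = np.vstack(chunks)
    session = Session(
        t=np.arange(angles.shape[0]) * dt,
        angles=angles,
        shoulder_pos=np.vstack(shoulder_chunks),
        events=events,
        morph=morph,
        rate=params.rate,
    )
    return results, session


def _max_still_run(positions: np.ndarray) -> int:
    """Longest run of consecutive below-threshold displacements, in steps."""
    if positions.shape[0] < 2:
        return 0
    step = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    still = step < STILL_TOL
    best = run = 0
    for s in still:
        run = run + 1 if s else 0
        best = max(best, run)
    return best


def clean_trials(session: Session):
    """Remove freezing/jumping trials; returns (cleaned session, removal report).

    Monitored positions are the shoulder and - when the session has full 7-DoF
    angles and a morphology - the hand centre (shoulder + forward kinematics),
    standing in for the body-mounted sensors of a motion-capture setup. The
    report lists ``{"trial": index, "reason": "freezing"|"jumping"}`` entries.
    """
    slices = session.trial_slices()
    if not slices:
        return session, []
    monitored = [session.shoulder_pos]
    if session.n_dofs == 7 and session.morph is not None:
        _, _, hand, _ = forward_kinematics_batch(session.angles, session.morph)
        monitored.append(session.shoulder_pos + hand)

    freeze_steps = math.ceil(FREEZE_DURATION * session.rate)
    report = []
    removed = set()
    for trial_no, (tgt, sl) in enumerate(slices):
        jump = np.linalg.norm(np.diff(session.shoulder_pos[sl], axis=0), axis=1)
        if jump.size and float(jump.max()) > JUMP_THRESHOLD:
            report.append({"trial": trial_no, "reason": "jumping"})
            removed.add(trial_no)
            continue
        for stream in monitored:
            if _max_still_run(stream[sl]) >= freeze_steps:
                report.append({"trial": trial_no, "reason": "freezing"})
                removed.add(trial_no)
                break

    if not removed:
        return session, report
    keep = np.ones(len(session), dtype=bool)
    removed_targets = set()
    for trial_no, (tgt, sl) in enumerate(slices):
        if trial_no in removed:
            keep[sl] = False
            removed_targets.add(tgt)
    events = [e for e in session.events if e.target_index not in removed_targets]
    cleaned = Session(
        t=session.t[keep],
        angles=session.angles[keep],
        shoulder_pos=session.shoulder_pos[keep],
        events=events,
        morph=session.morph,
        rate=session.rate,
    )
    return cleaned, report


def success_rate(results) -> float:
    """Percentage of successful trials."""
    if len(results) == 0:
        raise ValueError("no trial results")
    return 100.0 * sum(r.success for r in results) / len(results)


def movement_times(results) -> list[float]:
    """Movement times of the successful trials only."""
    if len(results) == 0:
        raise ValueError("no trial results")
    return [r.movement_time for r in results if r.success]


def _mvee(points: np.ndarray, tol: float = 1e-7, max_iter: int = 100_000):
    """Khachiyan's algorithm: minimum-volume enclosing ellipsoid of points.

    Returns (A, c) with the ellipsoid {x : (x-c)^T A (x-c) <= 1}.
    """
    p = np.asarray(points, dtype=float)
    n, d = p.shape
    q = np.column_stack([p, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x = q @ (u[:, None] * q.T)
        m = np.einsum("ij,ji->i", q.T, np.linalg.solve(x, q))
        j = int(np.argmax(m))
        maximum = m[j]
        if maximum <= d + 1 + tol * (d + 1):
            break
        step = (maximum - d - 1.0) / ((d + 1) * (maximum - 1.0))
        u *= 1.0 - step
        u[j] += step
    c = p.T @ u
    cov = p.T @ (u[:, None] * p) - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    return a, c


def spread_volume(shoulder_positions: np.ndarray, coverage: float = 0.9) -> float:
    """Volume (dm^3) of the minimum ellipsoid enclosing ``coverage`` of the points.

    The ``coverage`` fraction of points closest to the centroid in Mahalanobis
    distance is kept, then the minimum-volume enclosing ellipsoid of the kept
    points is computed; degenerate (coplanar or tighter) clouds give volume 0
    with a warning.
    """
    pts = np.asarray(shoulder_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) positions, got {pts.shape}")
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 positions")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")

    center = pts.mean(axis=0)
    x = pts - center
    cov = (x.T @ x) / pts.shape[0]
    if np.linalg.matrix_rank(cov, tol=1e-12) < 3:
        warnings.warn("degenerate shoulder-position cloud; spread volume set to 0")
        return 0.0
    d2 = np.einsum("ij,ij->i", x @ np.linalg.inv(cov), x)
    k = max(int(round(coverage * pts.shape[0])), 4)
    kept = pts[np.argsort(d2)[:k]]
    if np.linalg.matrix_rank(kept - kept.mean(axis=0), tol=1e-12) < 3:
        warnings.warn("degenerate shoulder-position cloud; spread volume set to 0")
        return 0.0

    # the MVEE touches only extreme points: reduce to the convex hull first
    try:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(kept)
        kept = kept[hull.vertices]
    except Exception:
        pass
    a, _ = _mvee(kept)
    det = np.linalg.det(a)
    if det <= 0:
        warnings.warn("degenerate ellipsoid; spread volume set to 0")
        return 0.0
    vol_m3 = (4.0 / 3.0) * math.pi / math.sqrt(det)
    return vol_m3 * 1000.0


def phase_metrics(results, shoulder_positions=None, n_trials_removed: int = 0) -> PhaseMetrics:
    """Summary metrics of a phase from its (cleaned) trial results."""
    sr = success_rate(results)
    mts = movement_times(results)
    sv = 0.0
    if shoulder_positions is not None and len(shoulder_positions) >= 10:
        sv = spread_volume(np.asarray(shoulder_positions))
    return PhaseMetrics(
        success_rate=sr,
        median_mt=float(np.median(mts)) if mts else None,
        spread_volume=sv,
        n_trials_kept=len(results),
        n_trials_removed=n_trials_removed,
    )
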