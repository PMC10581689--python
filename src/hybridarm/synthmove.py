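"""Synthetic natural-movement sessions.

Real training data for the distal-joint predictor comes from motion-tracked
pick-and-place sessions recorded at 90 Hz. This module generates equivalent
synthetic sessions so the whole pipeline runs without recordings: a
deterministic swivel-angle synergy resolves the arm's redundancy to give a
closed-form inverse-kinematics posture for any reachable target, and
fifth-order minimum-jerk interpolation in joint space strings those postures
into smooth 90 Hz trajectories with optional Gaussian angle jitter.

Because the generated proximal/distal coordination is a deterministic function
of the proximal angles and the hand location, a network trained on these
sessions can in principle recover the generating synergy exactly - which is
what makes parameter-recovery testing of the controller meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinematics import (
    ArmMorphology,
    HandLocation,
    JointAngles,
    _rot_x,
    _rot_y,
    _rot_z,
    axis_from_spherical,
    forward_kinematics_batch,
    mirror_angles,
    mirror_location,
)

__all__ = [
    "SynergyParams",
    "SessionEvent",
    "Session",
    "synergy_ik",
    "min_jerk_trajectory",
    "generate_session",
    "generate_rom_sweep_session",
    "inject_freezing",
    "inject_jumping",
    "REST_ANGLES",
]

#: mildly flexed start posture used at the beginning of every synthetic session
REST_ANGLES = JointAngles(s_fe=0.35, s_aa=0.25, h_r=0.0, e_fe=1.2, f_ps=0.0, w_fe=0.0, w_ru=0.0)


@dataclass(frozen=True)
class SynergyParams:
    """Parameters of the synthetic movement generator.

    swivel : elbow-drop angle (rad) fixing the arm's redundant DoF.
    noise_sd : per-sample, per-DoF Gaussian angle jitter (rad).
    rate : sampling rate in Hz.
    move_duration : duration of one point-to-point movement in seconds.
    shoulder_jitter_sd : per-sample shoulder-position jitter (m), emulating a
        seated subject keeping their back against the chair.
    """

    swivel: float = 0.3
    noise_sd: float = math.radians(0.5)
    rate: float = 90.0
    move_duration: float = 1.3
    shoulder_jitter_sd: float = 5e-4

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.move_duration <= 0:
            raise ValueError("move_duration must be positive")


@dataclass(frozen=True)
class SessionEvent:
    t: float
    kind: str  # target_shown | validated | timeout
    target_index: int


@dataclass
class Session:
    """A timestamped movement recording plus trial events.

    ``t`` is (n,), ``angles`` (n, 7) radians in canonical column order,
    ``shoulder_pos`` (n, 3) metres.
    """

    t: np.ndarray
    angles: np.ndarray
    shoulder_pos: np.ndarray
    events: list[SessionEvent] = field(default_factory=list)
    morph: ArmMorphology | None = None
    rate: float = 90.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.shoulder_pos = np.asarray(self.shoulder_pos, dtype=float)
        n = self.t.shape[0]
        if self.angles.shape[0] != n or self.shoulder_pos.shape[0] != n:
            raise ValueError("t, angles and shoulder_pos must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def n_dofs(self) -> int:
        return self.angles.shape[1]

    def trial_slices(self) -> list[tuple[int, slice]]:
        """(target_index, sample slice) per trial, delimited by target_shown events."""
        shown = [e for e in self.events if e.kind == "target_shown"]
        out = []
        for i, ev in enumerate(shown):
            start = int(np.searchsorted(self.t, ev.t))
            stop = (
                int(np.searchsorted(self.t, shown[i + 1].t)) if i + 1 < len(shown) else len(self)
            )
            out.append((ev.target_index, slice(start, stop)))
        return out


def _check_reachable(loc: HandLocation, morph: ArmMorphology) -> np.ndarray:
    """Validate reachability and return the wrist position for a right-side chain."""
    p = loc.center
    r = float(np.linalg.norm(p))
    if r > 0.98 * morph.arm_length or r < 0.2 * morph.arm_length:
        raise ValueError(
            f"target at {r:.3f} m is outside the reachable shell "
            f"[{0.2 * morph.arm_length:.3f}, {0.98 * morph.arm_length:.3f}] m"
        )
    w = p - morph.hand_len * axis_from_spherical(loc.incl, loc.azim)
    rw = float(np.linalg.norm(w))
    l1, l2 = morph.upper_arm_len, morph.forearm_len
    if rw > 0.999 * (l1 + l2) or rw < abs(l1 - l2) + 1e-4:
        raise ValueError(
            f"wrist distance {rw:.3f} m incompatible with segment lengths "
            f"({l1:.3f}, {l2:.3f}) m"
        )
    return w


def synergy_ik(
    target: HandLocation, morph: ArmMorphology, params: SynergyParams | None = None
) -> JointAngles:
    """Closed-form posture reaching a target under the swivel synergy.

    Elbow flexion follows from the law of cosines on the shoulder-to-wrist
    distance; the elbow circle is resolved by ``params.swivel``; forearm
    pronation-supination follows a fixed linear synergy of the target azimuth
    and the remaining wrist angles align the hand axis exactly. The forward
    kinematics of the returned posture reproduces the target to numerical
    precision.
    """
    if params is None:
        params = SynergyParams()
    if morph.side == "left":
        q = synergy_ik(mirror_location(target), replace(morph, side="right"), params)
        return mirror_angles(q)

    w = _check_reachable(target, morph)
    rw = float(np.linalg.norm(w))
    l1, l2 = morph.upper_arm_len, morph.forearm_len

    cos_gamma = np.clip((l1**2 + l2**2 - rw**2) / (2 * l1 * l2), -1.0, 1.0)
    e_fe = math.pi - math.acos(cos_gamma)

    # elbow on the circle around the shoulder-wrist axis, at the swivel angle
    u = w / rw
    cos_beta = np.clip((l1**2 + rw**2 - l2**2) / (2 * l1 * rw), -1.0, 1.0)
    beta = math.acos(cos_beta)
    down = np.array([0.0, 0.0, -1.0])
    a = down - np.dot(down, u) * u
    if np.linalg.norm(a) < 1e-9:
        a = np.array([1.0, 0.0, 0.0]) - u[0] * u
    a /= np.linalg.norm(a)
    b = np.cross(u, a)
    phi = params.swivel
    elbow = l1 * (math.cos(beta) * u + math.sin(beta) * (math.cos(phi) * a + math.sin(phi) * b))

    d1 = elbow / l1
    s_aa = math.asin(np.clip(-d1[1], -1.0, 1.0))
    s_fe = math.atan2(d1[0], -d1[2])

    r12 = _rot_y(-s_fe) @ _rot_x(-s_aa)
    v = r12.T @ (w - elbow) / l2  # = (sin e_fe cos h_r, -sin e_fe sin h_r, -cos e_fe)
    h_r = math.atan2(-v[1], v[0]) if math.sin(e_fe) > 1e-9 else 0.0

    # wrist angles aligning the hand axis, with f_ps set by a fixed synergy
    # (smooth and periodic in the axis azimuth, so the generated coordination
    # is continuous over the whole workspace)
    f_ps = 0.4 * math.sin(target.azim) * math.sin(target.incl)
    r_fore = r12 @ _rot_z(-h_r) @ _rot_y(-e_fe)
    h_loc = r_fore.T @ axis_from_spherical(target.incl, target.azim)
    g = _rot_z(f_ps) @ h_loc
    w_ru = math.asin(np.clip(-g[1], -1.0, 1.0))
    w_fe = math.atan2(g[0], -g[2])

    return JointAngles(s_fe, s_aa, h_r, e_fe, f_ps, w_fe, w_ru)


def min_jerk_trajectory(
    start: JointAngles, goal: JointAngles, duration: float, rate: float
) -> np.ndarray:
    """Per-DoF fifth-order minimum-jerk interpolation between two postures.

    Returns round(duration * rate) samples spanning [0, duration] inclusive,
    with exact endpoints and vanishing endpoint velocity and acceleration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = max(int(round(duration * rate)), 2)
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    q0 = start.to_array()
    q1 = goal.to_array()
    return q0[None, :] + s[:, None] * (q1 - q0)[None, :]


def _within_zone(
    angles: np.ndarray, morph: ArmMorphology, loc: HandLocation, pos_tol: float, ang_tol: float
) -> bool:
    _, _, center, axis = forward_kinematics_batch(angles[None, :], morph)
    pos_err = float(np.linalg.norm(center[0] - loc.center))
    ang_err = float(np.arccos(np.clip(np.dot(axis[0], loc.axis), -1.0, 1.0)))
    return pos_err <= pos_tol and ang_err <= ang_tol


def generate_session(
    targets: Sequence,
    morph: ArmMorphology,
    params: SynergyParams | None = None,
    seed: int = 0,
) -> Session:
    """Synthetic pick-and-place session visiting ``targets`` in order.

    Each element of ``targets`` may be a :class:`HandLocation` or any object
    with a ``location`` attribute (e.g. a Target). Successive synergy postures
    are joined by minimum-jerk movements with Gaussian angle jitter; a
    ``target_shown`` event marks each movement onset and a ``validated`` event
    marks each arrival within the hard tolerance (2 cm, 5 deg), ``timeout``
    otherwise. The shoulder stays at the origin up to a small seeded jitter.
    """
    if params is None:
        params = SynergyParams()
    if len(targets) == 0:
        raise ValueError("need at least one target")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.rate

    locs: list[HandLocation] = []
    for i, tg in enumerate(targets):
        loc = tg.location if hasattr(tg, "location") else tg
        locs.append(loc)

    current = REST_ANGLES if morph.side == "right" else mirror_angles(REST_ANGLES)
    chunks: list[np.ndarray] = []
    events: list[SessionEvent] = []
    n_total = 0
    for i, loc in enumerate(locs):
        try:
            goal = synergy_ik(loc, morph, params)
        except ValueError as exc:
            raise ValueError(f"target {i} is unreachable: {exc}") from exc
        traj = min_jerk_trajectory(current, goal, params.move_duration, params.rate)
        if chunks:
            traj = traj[1:]
        events.append(SessionEvent(t=n_total * dt, kind="target_shown", target_index=i))
        if params.noise_sd > 0:
            traj = traj + rng.normal(0.0, params.noise_sd, traj.shape)
        chunks.append(traj)
        n_total += traj.shape[0]
        arrived = _within_zone(traj[-1], morph, loc, 0.02, math.radians(5.0))
        events.append(
            SessionEvent(
                t=(n_total - 1) * dt,
                kind="validated" if arrived else "timeout",
                target_index=i,
            )
        )
        current = goal

    angles = np.vstack(chunks)
    n = angles.shape[0]
    t = np.arange(n) * dt
    shoulder = rng.normal(0.0, params.shoulder_jitter_sd, (n, 3))
    return Session(t=t, angles=angles, shoulder_pos=shoulder, events=events, morph=morph, rate=params.rate)


def generate_rom_sweep_session(
    bounds: np.ndarray,
    morph: ArmMorphology,
    params: SynergyParams | None = None,
    seed: int = 0,
    reps: int = 2,
) -> Session:
    """Elementary per-DoF sweeps across given bounds, for ROM estimation.

    ``bounds`` is (7, 2) of per-DoF (min, max) radians. Starting from the
    mid-range posture, each DoF in turn travels mid -> max -> min -> mid,
    ``reps`` times, while the others hold. The observed extrema of a
    noise-free sweep equal the bounds exactly.
    """
    if params is None:
        params = SynergyParams()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (7, 2):
        raise ValueError(f"bounds must be (7, 2), got {bounds.shape}")
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("each DoF needs min < max")
    rng = np.random.default_rng(seed)
    mid = bounds.mean(axis=1)
    dt = 1.0 / params.rate
    leg = max(int(round(0.6 * params.rate)), 2)

    chunks = []
    for d in range(7):
        for _ in range(reps):
            for lo, hi in ((mid[d], bounds[d, 1]), (bounds[d, 1], bounds[d, 0]), (bounds[d, 0], mid[d])):
                tau = np.linspace(0.0, 1.0, leg)
                s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
                q = np.tile(mid, (leg, 1))
                q[:, d] = lo + s * (hi - lo)
                chunks.append(q if not chunks else q[1:])
    angles = np.vstack(chunks)
    if params.noise_sd > 0:
        angles = angles + rng.normal(0.0, params.noise_sd, angles.shape)
    n = angles.shape[0]
    t = np.arange(n) * dt
    shoulder = rng.normal(0.0, params.shoulder_jitter_sd, (n, 3))
    return Session(t=t, angles=angles, shoulder_pos=shoulder, morph=morph, rate=params.rate)


def inject_freezing(session: Session, trial_index: int, duration: float = 0.6) -> Session:
    """Copy of the session with the shoulder held perfectly still for
    ``duration`` seconds inside one trial, emulating a tracker dropout."""
    slices = session.trial_slices()
    if not 0 <= trial_index < len(slices):
        raise IndexError(f"no trial {trial_index}")
    _, sl = slices[trial_index]
    shoulder = session.shoulder_pos.copy()
    n_freeze = min(int(math.ceil(duration * session.rate)) + 1, sl.stop - sl.start)
    shoulder[sl.start : sl.start + n_freeze] = shoulder[sl.start]
    return Session(
        t=session.t.copy(),
        angles=session.angles.copy(),
        shoulder_pos=shoulder,
        events=list(session.events),
        morph=session.morph,
        rate=session.rate,
    )


def inject_jumping(session: Session, trial_index: int, magnitude: float = 0.02) -> Session:
    """Copy of the session with a single-sample shoulder jump of ``magnitude``
    metres inside one trial, emulating a tracking glitch."""
    slices = session.trial_slices()
    if not 0 <= trial_index < len(slices):
        raise IndexError(f"no trial {trial_index}")
    _, sl = slices[trial_index]
    shoulder = session.shoulder_pos.copy()
    mid = (sl.start + sl.stop) // 2
    shoulder[mid:] = shoulder[mid:] + np.array([magnitude, 0.0, 0.0])
    return Session(
        t=session.t.copy(),
        angles=session.angles.copy(),
        shoulder_pos=shoulder,
        events=list(session.events),
        morph=session.morph,
        rate=session.rate,
    )
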