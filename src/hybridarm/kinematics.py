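"""7-DoF arm kinematics.

The arm is modelled as three rigid segments (upper arm, forearm, hand) driven
by seven anatomical joint angles: shoulder flexion-extension (s_fe), shoulder
abduction-adduction (s_aa), humeral rotation (h_r), elbow flexion-extension
(e_fe), forearm pronation-supination (f_ps), wrist flexion-extension (w_fe)
and wrist radial-ulnar deviation (w_ru).

Frame convention (fixed throughout the package): shoulder at the origin,
x anterior, y toward the subject's left, z up, right-handed. The zero posture
hangs the arm straight down along -z with the hand axis along -z. Rotation
sequence is intrinsic: s_fe about y, s_aa about x', h_r about the humeral
axis, e_fe about the elbow axis, f_ps about the forearm axis, then w_fe and
w_ru. Positive s_fe raises the arm forward (+x); positive s_aa abducts a
right arm laterally (-y); positive e_fe flexes the forearm forward.

The hand axis is the grasp/approach axis used for target matching: the unit
vector from the wrist to the hand center. Its orientation is reported as two
spherical angles relative to vertical - inclination ``incl`` in [0, pi]
measured from +z, and azimuth ``azim`` in (-pi, pi] about +z, set to 0 by
convention when the axis is vertical.

All angles are radians and all lengths metres; degrees appear only at file
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ANGLE_NAMES",
    "DISTAL_NAMES",
    "PROXIMAL_NAMES",
    "JointAngles",
    "ArmMorphology",
    "HandLocation",
    "ArmPosture",
    "forward_kinematics",
    "forward_kinematics_batch",
    "hand_location",
    "hand_locations_batch",
    "humeral_rotation_from_centers",
    "remap_hand_locations",
    "mirror_angles",
    "mirror_location",
    "mirror",
    "axis_from_spherical",
    "spherical_from_axis",
]

ANGLE_NAMES = ("s_fe", "s_aa", "h_r", "e_fe", "f_ps", "w_fe", "w_ru")
PROXIMAL_NAMES = ANGLE_NAMES[:2]
DISTAL_NAMES = ANGLE_NAMES[2:]

#: sign flips turning a right-side posture into its mirror-image left-side one
_MIRROR_SIGNS = np.array([1.0, -1.0, -1.0, 1.0, -1.0, 1.0, -1.0])

_VERTICAL_TOL = 1e-12


@dataclass(frozen=True)
class JointAngles:
    """The seven anatomical joint angles, in radians."""

    s_fe: float = 0.0
    s_aa: float = 0.0
    h_r: float = 0.0
    e_fe: float = 0.0
    f_ps: float = 0.0
    w_fe: float = 0.0
    w_ru: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.s_fe, self.s_aa, self.h_r, self.e_fe, self.f_ps, self.w_fe, self.w_ru]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "JointAngles":
        a = np.asarray(a, dtype=float)
        if a.shape != (7,):
            raise ValueError(f"expected 7 joint angles, got shape {a.shape}")
        return cls(*a.tolist())

    @property
    def proximal(self) -> np.ndarray:
        return self.to_array()[:2]

    @property
    def distal(self) -> np.ndarray:
        return self.to_array()[2:]


@dataclass(frozen=True)
class ArmMorphology:
    """Segment lengths (metres) and body side of the kinematic chain."""

    upper_arm_len: float
    forearm_len: float
    hand_len: float
    side: str = "right"

    def __post_init__(self) -> None:
        for name in ("upper_arm_len", "forearm_len", "hand_len"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite length, got {v}")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")

    @property
    def arm_length(self) -> float:
        return self.upper_arm_len + self.forearm_len + self.hand_len

    def mirrored(self) -> "ArmMorphology":
        return replace(self, side="left" if self.side == "right" else "right")


@dataclass(frozen=True)
class HandLocation:
    """5-parameter hand location: centre position + hand-axis orientation.

    ``incl`` is the angle of the hand axis from vertical (+z) in [0, pi];
    ``azim`` its azimuth about +z in (-pi, pi].
    """

    x: float
    y: float
    z: float
    incl: float
    azim: float

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.incl, self.azim])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "HandLocation":
        a = np.asarray(a, dtype=float)
        if a.shape != (5,):
            raise ValueError(f"expected 5 hand-location parameters, got shape {a.shape}")
        return cls(*a.tolist())

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def axis(self) -> np.ndarray:
        return axis_from_spherical(self.incl, self.azim)


@dataclass(frozen=True)
class ArmPosture:
    """Joint centres, hand centre and hand axis of a posture (shoulder frame)."""

    shoulder: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray
    hand_center: np.ndarray
    hand_axis: np.ndarray
    angles: JointAngles


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rot_x_batch(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    c, s = np.cos(a), np.sin(a)
    r = np.zeros((n, 3, 3))
    r[:, 0, 0] = 1.0
    r[:, 1, 1] = c
    r[:, 1, 2] = -s
    r[:, 2, 1] = s
    r[:, 2, 2] = c
    return r


def _rot_y_batch(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    c, s = np.cos(a), np.sin(a)
    r = np.zeros((n, 3, 3))
    r[:, 1, 1] = 1.0
    r[:, 0, 0] = c
    r[:, 0, 2] = s
    r[:, 2, 0] = -s
    r[:, 2, 2] = c
    return r


def _rot_z_batch(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    c, s = np.cos(a), np.sin(a)
    r = np.zeros((n, 3, 3))
    r[:, 2, 2] = 1.0
    r[:, 0, 0] = c
    r[:, 0, 1] = -s
    r[:, 1, 0] = s
    r[:, 1, 1] = c
    return r


def axis_from_spherical(incl: float, azim: float) -> np.ndarray:
    """Unit vector at inclination ``incl`` from +z and azimuth ``azim`` about +z."""
    si = np.sin(incl)
    return np.array([si * np.cos(azim), si * np.sin(azim), np.cos(incl)])


def spherical_from_axis(axis: np.ndarray) -> tuple[float, float]:
    """(incl, azim) of a unit axis; azim = 0 by convention on the vertical axis."""
    ax = np.asarray(axis, dtype=float)
    incl = float(np.arccos(np.clip(ax[2], -1.0, 1.0)))
    if abs(ax[0]) < _VERTICAL_TOL and abs(ax[1]) < _VERTICAL_TOL:
        return incl, 0.0
    return incl, float(np.arctan2(ax[1], ax[0]))


def _wrap_azim(a: np.ndarray | float):
    """Wrap azimuth(s) to (-pi, pi]."""
    w = -(np.mod(-np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi)
    return w


def forward_kinematics_batch(
    angles: np.ndarray, morph: ArmMorphology
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised forward kinematics.

    Parameters
    ----------
    angles : (n, 7) array of joint angles, columns in :data:`ANGLE_NAMES` order.
    morph : arm morphology; for ``side='left'`` the chain is the mirror image
        of the right-side chain across the medial (x-z) plane.

    Returns
    -------
    elbow, wrist, hand_center : (n, 3) joint-centre positions (shoulder frame)
    hand_axis : (n, 3) unit wrist-to-hand-centre directions
    """
    q = np.atleast_2d(np.asarray(angles, dtype=float))
    if q.shape[1] != 7:
        raise ValueError(f"expected (n, 7) joint angles, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("joint angles must be finite")

    if morph.side == "left":
        q = q * _MIRROR_SIGNS

    r_u = _rot_y_batch(-q[:, 0]) @ _rot_x_batch(-q[:, 1]) @ _rot_z_batch(-q[:, 2])
    r_f = r_u @ _rot_y_batch(-q[:, 3]) @ _rot_z_batch(-q[:, 4])
    r_h = r_f @ _rot_y_batch(-q[:, 5]) @ _rot_x_batch(-q[:, 6])

    down = np.array([0.0, 0.0, -1.0])
    elbow = morph.upper_arm_len * (r_u @ down)
    wrist = elbow + morph.forearm_len * (r_f @ down)
    hand_axis = r_h @ down
    hand_center = wrist + morph.hand_len * hand_axis

    if morph.side == "left":
        flip = np.array([1.0, -1.0, 1.0])
        elbow = elbow * flip
        wrist = wrist * flip
        hand_center = hand_center * flip
        hand_axis = hand_axis * flip

    return elbow, wrist, hand_center, hand_axis


def forward_kinematics(angles: JointAngles, morph: ArmMorphology) -> ArmPosture:
    """Joint centres and hand location of a single posture."""
    q = angles.to_array()[None, :]
    elbow, wrist, hand_center, hand_axis = forward_kinematics_batch(q, morph)
    return ArmPosture(
        shoulder=np.zeros(3),
        elbow=elbow[0],
        wrist=wrist[0],
        hand_center=hand_center[0],
        hand_axis=hand_axis[0],
        angles=angles,
    )


def hand_locations_batch(angles: np.ndarray, morph: ArmMorphology) -> np.ndarray:
    """Vectorised hand locations, returned as an (n, 5) array (x, y, z, incl, azim)."""
    _, _, center, axis = forward_kinematics_batch(angles, morph)
    incl = np.arccos(np.clip(axis[:, 2], -1.0, 1.0))
    azim = np.arctan2(axis[:, 1], axis[:, 0])
    vertical = (np.abs(axis[:, 0]) < _VERTICAL_TOL) & (np.abs(axis[:, 1]) < _VERTICAL_TOL)
    azim = np.where(vertical, 0.0, azim)
    return np.column_stack([center, incl, azim])


def hand_location(angles: JointAngles, morph: ArmMorphology) -> HandLocation:
    """The 5-parameter hand location reached by a posture."""
    loc = hand_locations_batch(angles.to_array()[None, :], morph)[0]
    return HandLocation.from_array(loc)


def humeral_rotation_from_centers(
    shoulder: np.ndarray,
    elbow: np.ndarray,
    wrist: np.ndarray,
    reference_axis: np.ndarray,
) -> float:
    """Signed rotation of the shoulder-elbow-wrist triangle's normal about the
    humeral (shoulder-to-elbow) axis, measured from ``reference_axis``.

    This is the joint-centre geometry used to recover humeral rotation, which
    a skin-mounted upper-arm sensor cannot measure reliably. The triangle
    degenerates when the arm is straight, hence the elbow-extension cap
    applied upstream when ranges of motion are estimated.
    """
    shoulder = np.asarray(shoulder, dtype=float)
    elbow = np.asarray(elbow, dtype=float)
    wrist = np.asarray(wrist, dtype=float)
    u = elbow - shoulder
    v = wrist - elbow
    n = np.cross(u, v)
    nn = np.linalg.norm(n)
    if nn < 1e-9 * max(np.linalg.norm(u) * np.linalg.norm(v), 1e-30):
        raise ValueError(
            "shoulder, elbow and wrist are (nearly) collinear: humeral rotation "
            "is undefined for a straight arm"
        )
    axis = u / np.linalg.norm(u)
    n = n / nn
    ref = np.asarray(reference_axis, dtype=float)
    # project both vectors into the plane normal to the humeral axis
    n_p = n - np.dot(n, axis) * axis
    r_p = ref - np.dot(ref, axis) * axis
    if np.linalg.norm(n_p) < 1e-12 or np.linalg.norm(r_p) < 1e-12:
        raise ValueError("reference axis is parallel to the humeral axis")
    n_p /= np.linalg.norm(n_p)
    r_p /= np.linalg.norm(r_p)
    return float(np.arctan2(np.dot(np.cross(r_p, n_p), axis), np.dot(r_p, n_p)))


def remap_hand_locations(
    angle_trajectory: np.ndarray | Sequence[JointAngles],
    target_morph: ArmMorphology,
) -> np.ndarray:
    """Hand locations a joint-angle trajectory produces under another morphology.

    The same angular configurations give different hand positions depending on
    segment lengths, so donor recordings must be remapped to the intended
    user's arm before they can serve as training context. Angles are left
    untouched; the (n, 5) array of remapped hand locations is returned.
    """
    if isinstance(angle_trajectory, np.ndarray):
        q = angle_trajectory
    else:
        traj = list(angle_trajectory)
        if len(traj) == 0:
            raise ValueError("empty angle trajectory")
        q = np.array([a.to_array() for a in traj])
    if q.size == 0:
        raise ValueError("empty angle trajectory")
    return hand_locations_batch(q, target_morph)


def mirror_angles(angles: JointAngles | np.ndarray):
    """Mirror a posture (or (n, 7) trajectory) across the medial plane.

    Sign-flips s_aa, h_r, f_ps and w_ru; flexion-type angles are unchanged.
    """
    if isinstance(angles, JointAngles):
        return JointAngles.from_array(angles.to_array() * _MIRROR_SIGNS)
    return np.asarray(angles, dtype=float) * _MIRROR_SIGNS


def mirror_location(loc: HandLocation | np.ndarray):
    """Mirror a hand location (or (n, 5) array) across the medial plane: y -> -y,
    azim -> -azim (wrapped to (-pi, pi])."""
    if isinstance(loc, HandLocation):
        return HandLocation(loc.x, -loc.y, loc.z, loc.incl, float(_wrap_azim(-loc.azim)))
    a = np.array(loc, dtype=float, copy=True)
    a[..., 1] = -a[..., 1]
    a[..., 4] = _wrap_azim(-a[..., 4])
    return a


def mirror(value):
    """Mirror joint angles or a hand location across the medial (x-z) plane."""
    if isinstance(value, JointAngles):
        return mirror_angles(value)
    if isinstance(value, HandLocation):
        return mirror_location(value)
    raise TypeError(f"cannot mirror object of type {type(value).__name__}")
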