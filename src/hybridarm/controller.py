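"""Goal-aware distal-joint prediction.

The controller learns the map from (proximal shoulder angles, goal location)
to the five distal joint angles - humeral rotation, elbow flexion-extension,
forearm pronation-supination, wrist flexion-extension and radial-ulnar
deviation - so that a hybrid arm can combine an operator's residual shoulder
motion with predicted distal joints.

Training uses the hand-location-as-target trick: goal-related context in the
training set is the hand location of each recorded sample itself, as if every
posture had brought the hand onto a hypothetical target. Targets in a task are
sparse and clustered, so training on true target locations yields
discontinuous, overfit-prone context signals; the hand location varies
continuously along whole trajectories and covers the workspace homogeneously,
turning the network into a natural inverse-kinematics regressor. At run time
the same inputs carry the actual target location instead.

Two training regimes exist. The *Own* model trains on the intended user's own
recordings. The *Generic* model trains on donor recordings from other
subjects: donor hand locations are recomputed (remapped) under the user's arm
morphology - because identical joint angles give different hand positions for
different segment lengths - while the outputs stay the donors' original
angles; donor sides are mirrored to the user's side first.

The API follows the model/results convention: build a
:class:`DistalJointModel` from data, call :meth:`~DistalJointModel.fit`, get a
:class:`DistalJointResults` carrying weights, normalisation, diagnostics and
``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinematics import (
    ANGLE_NAMES,
    ArmMorphology,
    ArmPosture,
    HandLocation,
    JointAngles,
    forward_kinematics,
    hand_locations_batch,
    mirror_angles,
)
from .mlp import MLP
from .synthmove import Session

__all__ = [
    "TrainingConfig",
    "PRESETS",
    "build_training_pairs",
    "build_generic_dataset",
    "DistalJointModel",
    "DistalJointResults",
    "train_model",
    "predict_distal",
    "hybrid_step",
]

INPUT_NAMES = ("s_fe", "s_aa", "x", "y", "z", "incl", "azim")
OUTPUT_NAMES = ANGLE_NAMES[2:]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """SGD training configuration.

    Learning rates are relative to z-scored inputs and outputs; the named
    presets in :data:`PRESETS` record the published hyperparameters of the Own
    and Generic regimes, whose original feature scaling is unknown, alongside
    the package default that converges well under z-scoring.
    """

    epochs: int = 30
    learning_rate: float = 0.01
    momentum: float | None = 0.95
    batch_size: int = 64
    seed: int = 0
    lr_decay: float = 0.93

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")


PRESETS: dict[str, TrainingConfig] = {
    "own": TrainingConfig(epochs=30, learning_rate=1e-4, momentum=None, lr_decay=1.0),
    "generic": TrainingConfig(
        epochs=10, learning_rate=1.59e-7, momentum=0.95, lr_decay=1.0
    ),
    "default": TrainingConfig(
        epochs=30, learning_rate=0.01, momentum=0.95, lr_decay=0.93
    ),
}


def build_training_pairs(session: Session, morph: ArmMorphology | None = None):
    """(X, Y) training arrays from a session, one pair per sample.

    X columns: s_fe, s_aa, then the sample's own hand location (x, y, z, incl,
    azim) under ``morph`` (defaults to the session's morphology). Y columns:
    the five distal angles of the same sample.
    """
    morph = morph or session.morph
    if morph is None:
        raise ValueError("session carries no morphology and none was given")
    if session.n_dofs != 7:
        raise ValueError(
            "session has only proximal DoFs (residual-limb recording): "
            "there are no distal outputs to learn"
        )
    locs = hand_locations_batch(session.angles, morph)
    x = np.column_stack([session.angles[:, :2], locs])
    y = session.angles[:, 2:]
    return x, y


def build_generic_dataset(
    sessions: Sequence[Session], user_morph: ArmMorphology
):
    """Concatenated donor pairs remapped to the intended user's morphology.

    Donor recordings from the opposite body side are mirrored to the user's
    side; context hand locations are recomputed under ``user_morph`` while the
    outputs remain the donors' (possibly mirrored) original distal angles.
    """
    if len(sessions) == 0:
        raise ValueError("need at least one donor session")
    xs, ys = [], []
    for k, ses in enumerate(sessions):
        if ses.morph is None:
            raise ValueError(f"donor session {k} carries no morphology metadata")
        if ses.n_dofs != 7:
            raise ValueError(f"donor session {k} lacks distal DoFs")
        angles = ses.angles
        if ses.morph.side != user_morph.side:
            angles = mirror_angles(angles)
        locs = hand_locations_batch(angles, user_morph)
        xs.append(np.column_stack([angles[:, :2], locs]))
        ys.append(angles[:, 2:])
    return np.vstack(xs), np.vstack(ys)


class DistalJointModel:
    """Distal-joint predictor specification, built from training pairs.

    Use :meth:`from_session` (Own regime) or :meth:`from_donor_sessions`
    (Generic regime); :meth:`fit` trains the network and returns a
    :class:`DistalJointResults`.
    """

    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        morph: ArmMorphology | None = None,
        provenance: str = "own",
    ):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or x.shape[1] != 7:
            raise ValueError(f"X must be (n, 7), got {x.shape}")
        if y.ndim != 2 or y.shape[1] != 5 or y.shape[0] != x.shape[0]:
            raise ValueError(f"Y must be (n, 5) matching X, got {y.shape}")
        self.x = x
        self.y = y
        self.morph = morph
        self.provenance = provenance

    @classmethod
    def from_session(cls, session: Session, morph: ArmMorphology | None = None):
        x, y = build_training_pairs(session, morph)
        return cls(x, y, morph or session.morph, provenance="own")

    @classmethod
    def from_donor_sessions(cls, sessions: Sequence[Session], user_morph: ArmMorphology):
        x, y = build_generic_dataset(sessions, user_morph)
        return cls(x, y, user_morph, provenance="generic")

    @property
    def nobs(self) -> int:
        return self.x.shape[0]

    def fit(
        self, config: TrainingConfig | str | None = None, min_pairs: int = 100
    ) -> "DistalJointResults":
        """Train the network by seeded mini-batch SGD and freeze normalisation.

        ``config`` may be a :class:`TrainingConfig` or a preset name
        ('own', 'generic', 'default'). Inputs and outputs are z-scored with
        statistics of this training set, stored with the weights; predictions
        are clipped to the per-DoF output range seen in training, emulating
        prosthesis joint limits.
        """
        if isinstance(config, str):
            try:
                config = PRESETS[config]
            except KeyError:
                raise ValueError(
                    f"unknown preset {config!r}; choose from {sorted(PRESETS)}"
                ) from None
        if config is None:
            config = PRESETS["default"]
        if self.nobs < min_pairs:
            raise ValueError(f"need at least {min_pairs} training pairs, got {self.nobs}")

        x_mean = self.x.mean(axis=0)
        x_std = self.x.std(axis=0)
        x_std[x_std < 1e-12] = 1.0
        y_mean = self.y.mean(axis=0)
        y_std = self.y.std(axis=0)
        y_std[y_std < 1e-12] = 1.0
        xn = (self.x - x_mean) / x_std
        yn = (self.y - y_mean) / y_std

        net = MLP(n_in=7, n_out=5, seed=config.seed)
        net.fit(
            xn,
            yn,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            batch_size=config.batch_size,
            seed=config.seed + 1,
            lr_decay=config.lr_decay,
        )
        resid = net.forward(xn) * y_std + y_mean - self.y
        train_rmse = np.sqrt(np.mean(resid**2, axis=0))
        return DistalJointResults(
            net=net,
            x_mean=x_mean,
            x_std=x_std,
            y_mean=y_mean,
            y_std=y_std,
            y_lo=self.y.min(axis=0),
            y_hi=self.y.max(axis=0),
            provenance=self.provenance,
            config=config,
            nobs=self.nobs,
            train_rmse=train_rmse,
        )


class DistalJointResults:
    """A trained distal-joint predictor with frozen normalisation.

    Inference is deterministic (dropout is inactive outside training) and
    outputs are clipped to the per-DoF training range.
    """

    def __init__(
        self,
        net: MLP,
        x_mean: np.ndarray,
        x_std: np.ndarray,
        y_mean: np.ndarray,
        y_std: np.ndarray,
        y_lo: np.ndarray,
        y_hi: np.ndarray,
        provenance: str,
        config: TrainingConfig,
        nobs: int,
        train_rmse: np.ndarray,
    ):
        self.net = net
        self.x_mean = x_mean
        self.x_std = x_std
        self.y_mean = y_mean
        self.y_std = y_std
        self.y_lo = y_lo
        self.y_hi = y_hi
        self.provenance = provenance
        self.config = config
        self.nobs = nobs
        self.train_rmse = train_rmse

    # -- inference -------------------------------------------------------------
    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        """(n, 7) inputs (s_fe, s_aa, x, y, z, incl, azim) -> (n, 5) distal angles."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != 7:
            raise ValueError(f"inputs must be (n, 7), got {x.shape}")
        xn = (x - self.x_mean) / self.x_std
        y = self.net.forward(xn) * self.y_std + self.y_mean
        return np.clip(y, self.y_lo, self.y_hi)

    def predict_distal(
        self, s_fe: float, s_aa: float, target: HandLocation
    ) -> np.ndarray:
        """The five distal angles for given proximal angles and goal location."""
        x = np.concatenate([[s_fe, s_aa], target.to_array()])
        return self.predict_batch(x[None, :])[0]

    # -- diagnostics -----------------------------------------------------------
    def rmse(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-DoF root-mean-square prediction error on held-out pairs (radians)."""
        resid = self.predict_batch(x) - np.asarray(y, dtype=float)
        return np.sqrt(np.mean(resid**2, axis=0))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Distal-joint predictor",
            "=" * 54,
            f"{'regime':<22}{self.provenance}",
            f"{'training pairs':<22}{self.nobs}",
            f"{'epochs':<22}{cfg.epochs}",
            f"{'learning rate':<22}{cfg.learning_rate:g}",
            f"{'momentum':<22}{cfg.momentum if cfg.momentum is not None else '-'}",
            f"{'batch size':<22}{cfg.batch_size}",
            f"{'final train loss':<22}{self.net.loss_history[-1]:.3e}",
            "-" * 54,
            f"{'output DoF':<14}{'train RMSE (deg)':>18}{'clip range (deg)':>22}",
        ]
        for i, name in enumerate(OUTPUT_NAMES):
            lines.append(
                f"{name:<14}{np.degrees(self.train_rmse[i]):>18.2f}"
                f"{np.degrees(self.y_lo[i]):>11.1f} {np.degrees(self.y_hi[i]):>9.1f}"
            )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------
    def save(self, path: str | Path, extra_meta: dict | None = None) -> None:
        """Write a portable single-file JSON archive of the trained model."""
        payload = {
            "format_version": _FORMAT_VERSION,
            "provenance": self.provenance,
            "config": asdict(self.config),
            "nobs": self.nobs,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "y_lo": self.y_lo.tolist(),
            "y_hi": self.y_hi.tolist(),
            "train_rmse": self.train_rmse.tolist(),
            "net": self.net.to_dict(),
        }
        if extra_meta:
            payload["meta"] = extra_meta
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DistalJointResults":
        d = json.loads(Path(path).read_text())
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {d.get('format_version')!r}"
            )
        return cls(
            net=MLP.from_dict(d["net"]),
            x_mean=np.array(d["x_mean"]),
            x_std=np.array(d["x_std"]),
            y_mean=np.array(d["y_mean"]),
            y_std=np.array(d["y_std"]),
            y_lo=np.array(d["y_lo"]),
            y_hi=np.array(d["y_hi"]),
            provenance=d["provenance"],
            config=TrainingConfig(**d["config"]),
            nobs=d["nobs"],
            train_rmse=np.array(d["train_rmse"]),
        )


def train_model(
    x: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | str | None = None,
    morph: ArmMorphology | None = None,
    provenance: str = "own",
) -> DistalJointResults:
    """Functional wrapper: train a predictor directly from (X, Y) pairs."""
    return DistalJointModel(x, y, morph, provenance).fit(config)


def predict_distal(
    results: DistalJointResults, s_fe: float, s_aa: float, target: HandLocation
) -> np.ndarray:
    """Functional wrapper around :meth:`DistalJointResults.predict_distal`."""
    return results.predict_distal(s_fe, s_aa, target)


def hybrid_step(
    model,
    operator_s_fe: float,
    operator_s_aa: float,
    target: HandLocation,
    morph: ArmMorphology,
) -> ArmPosture:
    """One step of hybrid-arm composition.

    The two proximal DoFs come straight from the operator; the five distal
    DoFs come from ``model`` (anything exposing ``predict_distal``); the
    forward kinematics of the assembled 7-DoF posture is returned.
    """
    distal = model.predict_distal(operator_s_fe, operator_s_aa, target)
    angles = JointAngles.from_array(
        np.concatenate([[operator_s_fe, operator_s_aa], np.asarray(distal, dtype=float)])
    )
    return forward_kinematics(angles, morph)
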