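"""File formats.

Sessions: a CSV (one row per sample: t_s, the seven joint angles in degrees,
shoulder x/y/z in metres) plus a JSON sidecar (same path, .json extension)
holding the sampling rate, morphology, trial events and provenance. Target
sets: CSV with index, role, x_m, y_m, z_m, incl_deg, azim_deg. Ranges of
motion and morphology: YAML/JSON blocks with angles in degrees. Angles are
degrees in files and radians in memory, always.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import ANGLE_NAMES, ArmMorphology, HandLocation
from .synthmove import Session, SessionEvent
from .targets import RangeOfMotion, Target

__all__ = [
    "read_session",
    "write_session",
    "read_targets",
    "write_targets",
    "read_rom",
    "write_rom",
    "read_morphology",
    "write_morphology",
    "config_hash",
    "provenance_block",
]

_SESSION_COLUMNS = ["t_s"] + [f"{n}_deg" for n in ANGLE_NAMES] + [
    "shoulder_x_m",
    "shoulder_y_m",
    "shoulder_z_m",
]
_TARGET_COLUMNS = ["index", "role", "x_m", "y_m", "z_m", "incl_deg", "azim_deg"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_block(seed: int | None, config) -> dict:
    return {"seed": seed, "config_hash": config_hash(config)}


def write_session(session: Session, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([session.t, np.degrees(session.angles), session.shoulder_pos]),
        columns=_SESSION_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "rate_hz": session.rate,
        "morphology": None
        if session.morph is None
        else {
            "upper_arm_len": session.morph.upper_arm_len,
            "forearm_len": session.morph.forearm_len,
            "hand_len": session.morph.hand_len,
            "side": session.morph.side,
        },
        "events": [
            {"t_s": e.t, "kind": e.kind, "target_index": e.target_index}
            for e in session.events
        ],
    }
    if provenance:
        sidecar["provenance"] = provenance
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def read_session(path: str | Path) -> Session:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing session column(s): {', '.join(missing)}")
    bad = df[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {int(bad.index[0]) + 2}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        i = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise ValueError(f"{path}: non-monotone timestamps at line {i + 3}")
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"{path}: missing sidecar {side.name}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{side}: truncated or invalid sidecar: {exc}") from exc
    for key in ("rate_hz", "events"):
        if key not in meta:
            raise ValueError(f"{side}: sidecar missing key {key!r}")
    morph = None
    if meta.get("morphology"):
        morph = ArmMorphology(**meta["morphology"])
    events = [
        SessionEvent(t=e["t_s"], kind=e["kind"], target_index=e["target_index"])
        for e in meta["events"]
    ]
    angles = np.radians(df[[f"{n}_deg" for n in ANGLE_NAMES]].to_numpy(dtype=float))
    shoulder = df[["shoulder_x_m", "shoulder_y_m", "shoulder_z_m"]].to_numpy(dtype=float)
    return Session(
        t=t, angles=angles, shoulder_pos=shoulder, events=events, morph=morph,
        rate=float(meta["rate_hz"]),
    )


def write_targets(targets: list[Target], path: str | Path, provenance: dict | None = None) -> None:
    rows = []
    for tg in targets:
        loc = tg.location
        rows.append(
            {
                "index": tg.index,
                "role": tg.role,
                "x_m": loc.x,
                "y_m": loc.y,
                "z_m": loc.z,
                "incl_deg": np.degrees(loc.incl),
                "azim_deg": np.degrees(loc.azim),
            }
        )
    df = pd.DataFrame(rows, columns=_TARGET_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    if provenance:
        _sidecar(path).write_text(json.dumps({"provenance": provenance}, indent=1))


def read_targets(path: str | Path) -> list[Target]:
    df = pd.read_csv(path)
    missing = [c for c in _TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing target column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        loc = HandLocation(
            float(row.x_m),
            float(row.y_m),
            float(row.z_m),
            float(np.radians(row.incl_deg)),
            float(np.radians(row.azim_deg)),
        )
        out.append(Target(location=loc, role=str(row.role), index=int(row["index"])))
    return out


def write_rom(rom: RangeOfMotion, path: str | Path) -> None:
    names = ANGLE_NAMES[: rom.n_dofs]
    block = {
        name: {
            "min_deg": float(np.degrees(rom.bounds[i, 0])),
            "max_deg": float(np.degrees(rom.bounds[i, 1])),
        }
        for i, name in enumerate(names)
    }
    Path(path).write_text(yaml.safe_dump({"rom": block}, sort_keys=False))


def read_rom(path: str | Path) -> RangeOfMotion:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "rom" not in doc:
        raise ValueError(f"{path}: not a ROM file (missing 'rom' block)")
    block = doc["rom"]
    names = [n for n in ANGLE_NAMES if n in block]
    if len(names) not in (2, 7):
        raise ValueError(f"{path}: ROM must define 2 or 7 DoFs, found {len(names)}")
    bounds = np.array(
        [
            [np.radians(block[n]["min_deg"]), np.radians(block[n]["max_deg"])]
            for n in names
        ]
    )
    return RangeOfMotion(bounds)


def write_morphology(morph: ArmMorphology, path: str | Path) -> None:
    block = {
        "upper_arm_len": morph.upper_arm_len,
        "forearm_len": morph.forearm_len,
        "hand_len": morph.hand_len,
        "side": morph.side,
    }
    Path(path).write_text(yaml.safe_dump({"morphology": block}, sort_keys=False))


def read_morphology(path: str | Path) -> ArmMorphology:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "morphology" not in doc:
        raise ValueError(f"{path}: not a morphology file (missing 'morphology' block)")
    return ArmMorphology(**doc["morphology"])
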