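"""Readers and writers for every external artifact.

Meshes are STL (ASCII or binary) or PLY via :mod:`trimesh`.  Landmark sets
are JSON (canonical) or CSV ``name,x,y,z,skipped``.  Engine configuration
is YAML or JSON validated through a pydantic model.  Proposal reports are
versioned JSON.  Readers reject malformed input instead of coercing it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pydantic
import trimesh
import yaml

from .errors import ConfigError, LandmarkError, MeshLoadError

REPORT_SCHEMA_VERSION = 1
LANDMARK_SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an STL or PLY surface mesh; raise :class:`MeshLoadError` on junk."""
    path = Path(path)
    if not path.exists():
        raise MeshLoadError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load_mesh(str(path))
    except BaseException as exc:  # trimesh raises a zoo of types
        raise MeshLoadError(f"cannot load mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshLoadError(f"{path} contains no usable triangulated surface")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

@dataclass
class Landmark:
    name: str
    position: np.ndarray
    skipped: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise LandmarkError(f"landmark '{self.name}' has non-finite position")


@dataclass
class LandmarkSet:
    """Named 3D landmarks with a per-entry skip flag.

    The skip flag marks sites the user could not place reliably; skipped
    entries survive round-trips but are excluded from registration.
    """

    entries: list[Landmark] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LandmarkError(f"duplicate landmark names: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> Landmark:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def active(self) -> "LandmarkSet":
        """Subset of non-skipped landmarks."""
        return LandmarkSet([Landmark(e.name, e.position.copy(), False)
                            for e in self.entries if not e.skipped])

    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=float)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmarks from JSON (canonical) or CSV ``name,x,y,z,skipped``."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            rows = [r for r in reader if r]
        if rows and rows[0][:2] == ["name", "x"]:
            rows = rows[1:]
        for row in rows:
            if len(row) not in (4, 5):
                raise LandmarkError(f"bad CSV landmark row: {row}")
            skipped = len(row) == 5 and row[4].strip().lower() in ("1", "true", "yes")
            try:
                pos = [float(row[1]), float(row[2]), float(row[3])]
            except ValueError as exc:
                raise LandmarkError(f"non-numeric coordinate in row {row}") from exc
            entries.append(Landmark(row[0].strip(), pos, skipped))
        return LandmarkSet(entries)
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkError(f"invalid landmark JSON in {path}: {exc}") from exc
    if not isinstance(data, dict) or "landmarks" not in data:
        raise LandmarkError(f"{path}: expected object with 'landmarks' list")
    entries = []
    for item in data["landmarks"]:
        try:
            entries.append(Landmark(item["name"], item["position"],
                                    bool(item.get("skipped", False))))
        except (KeyError, TypeError) as exc:
            raise LandmarkError(f"malformed landmark entry {item}") from exc
    return LandmarkSet(entries)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z", "skipped"])
            for e in landmarks:
                writer.writerow([e.name, repr(float(e.position[0])),
                                 repr(float(e.position[1])),
                                 repr(float(e.position[2])), int(e.skipped)])
        return
    payload = {
        "schema_version": LANDMARK_SCHEMA_VERSION,
        "landmarks": [
            {"name": e.name, "position": [float(x) for x in e.position],
             "skipped": bool(e.skipped)}
            for e in landmarks
        ],
    }
    path.write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# engine configuration
# --------------------------------------------------------------------------

DEFAULT_WEIGHTS = {
    "midline_fidelity": 1.0,
    "symmetry": 1.0,
    "surface_continuity": 1.0,
    "pedicle_feasibility": 1.0,
}


class EngineConfig(pydantic.BaseModel):
    """Tunable parameters of the proposal engine.

    The default weighting is balanced: every enabled analysis contributes
    equally to the total score.  All lengths are millimetres.
    """

    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)

    level: Literal["basal", "middle", "apical"] = "basal"
    weights: dict[str, float] = pydantic.Field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    min_segment_length: float = 2.5
    donor_filter: Optional[Literal["left_fibula", "right_fibula"]] = None
    pedicle_filter: Optional[Literal["left", "right"]] = None
    skin_island_filter: Optional[Literal["none", "lateral", "medial"]] = None
    allow_mono_segment: bool = True
    midline_step: float = 0.5
    seed: int = 0

    max_segments: int = 4
    max_segment_length: float = 40.0
    min_practical_segment_length: float = 15.0
    kerf: float = 1.0
    tau_midline: float = 5.0
    tau_symmetry: float = 5.0
    pedicle_max_length: float = 80.0
    snap_max_distance: float = 40.0
    short_segment_threshold: float = 2.5
    refine_continuous: bool = True
    refine_min_step: float = 0.05

    @pydantic.field_validator("weights")
    @classmethod
    def _check_weights(cls, w: dict[str, float]) -> dict[str, float]:
        unknown = set(w) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ValueError(
                f"unknown score criteria {sorted(unknown)}; "
                f"valid: {sorted(DEFAULT_WEIGHTS)}")
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        merged = dict(DEFAULT_WEIGHTS)
        merged.update(w)
        if all(v == 0 for v in merged.values()):
            raise ValueError("at least one weight must be positive")
        return merged

    @pydantic.field_validator("min_segment_length", "midline_step",
                              "max_segment_length", "min_practical_segment_length")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v


def read_config(path: str | Path) -> EngineConfig:
    """Load an engine configuration from YAML or JSON."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return EngineConfig(**raw)
    except pydantic.ValidationError as exc:
        valid = sorted(EngineConfig.model_fields)
        raise ConfigError(f"invalid config {path}: {exc}; valid keys: {valid}") from exc


def write_config(config: EngineConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = json.loads(config.model_dump_json())
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# proposal reports
# --------------------------------------------------------------------------

def write_report(proposals, path: str | Path, extra: Optional[dict] = None) -> None:
    """Write a versioned JSON report of planning proposals.

    ``proposals`` may be objects exposing ``to_dict()`` or plain dicts.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [p.to_dict() if hasattr(p, "to_dict") else dict(p) for p in proposals]
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "proposals": records}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported report schema_version {data.get('schema_version')!r}")
    return data
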