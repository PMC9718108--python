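"""Readers and writers for landmark point files and per-hip clinical tables.

Landmark files use a small plain-text dialect::

    version: 1
    n_points: 82
    {
    <x> <y>
    ...82 coordinate lines...
    }

Coordinates are millimetres in a y-up frame (image pixel coordinates, which
are y-down, must be flipped at ingestion so the mirroring axis is
unambiguous).  Per-hip metadata (participant id, side, sex) is taken from a
JSON sidecar ``<stem>.meta.json`` when one exists, otherwise parsed from a
``<participant>_<side>.pts`` filename.

The clinical table is a CSV with one row per hip; see :class:`HipRecord` for
the column schema.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of landmark points in a hip configuration (femoral head arc,
#: head-neck junction, lateral and medial neck, acetabular rim).
N_POINTS = 82

SIDES = ("left", "right")
SEXES = ("male", "female")
STATUS_LEVELS = ("symptomatic", "other", "asymptomatic")

CARTILAGE_COLS = tuple(f"cartilage_{i}" for i in range(1, 11))
LABRAL_COLS = tuple(f"labral_{i}" for i in range(1, 5))
HIP_TABLE_COLS = (
    "participant_id",
    "side",
    "sex",
    "age",
    "bmi",
    "symptomatic_status",
    "kl_grade",
) + CARTILAGE_COLS + LABRAL_COLS


class PointsFileError(ValueError):
    """Base class for landmark-file format errors."""


class MalformedHeaderError(PointsFileError):
    """Header lines do not match the ``version`` / ``n_points`` / ``{`` layout."""


class WrongPointCountError(PointsFileError):
    """Declared or actual point count differs from the 82-point schema."""


class InvalidCoordinateError(PointsFileError):
    """A coordinate line could not be parsed as two finite numbers."""


class ClinicalTableError(ValueError):
    """Schema or range violation in a clinical hip table."""


@dataclass
class LandmarkConfiguration:
    """One hip's ordered 82-point 2-D landmark configuration plus metadata."""

    hip_id: str
    participant_id: str
    side: str
    points: np.ndarray
    sex: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_POINTS, 2):
            raise WrongPointCountError(
                f"wrong point count: expected {N_POINTS} (x, y) points, "
                f"got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidCoordinateError("landmark coordinates must be finite")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES} or None, got {self.sex!r}")
        self.points = pts


_HEADER_RE = re.compile(r"^version:\s*(\d+)\s*$")
_NPOINTS_RE = re.compile(r"^n_points:\s*(\d+)\s*$")


def read_points_file(path: str | Path) -> LandmarkConfiguration:
    """Parse a ``.pts`` landmark file into a :class:`LandmarkConfiguration`.

    Raises
    ------
    MalformedHeaderError, WrongPointCountError, InvalidCoordinateError
        For the corresponding dialect violations.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 4:
        raise MalformedHeaderError(f"{path}: file too short to contain a header")
    m = _HEADER_RE.match(lines[0])
    if m is None:
        raise MalformedHeaderError(
            f"{path}: first line must be 'version: <int>', got {lines[0]!r}"
        )
    m = _NPOINTS_RE.match(lines[1])
    if m is None:
        raise MalformedHeaderError(
            f"{path}: second line must be 'n_points: <int>', got {lines[1]!r}"
        )
    declared = int(m.group(1))
    if declared != N_POINTS:
        raise WrongPointCountError(
            f"{path}: wrong point count: declared n_points: {declared}, "
            f"this schema requires {N_POINTS}"
        )
    if lines[2] != "{":
        raise MalformedHeaderError(f"{path}: expected '{{' after header, got {lines[2]!r}")
    if lines[-1] != "}":
        raise MalformedHeaderError(f"{path}: expected closing '}}' as last line")
    coord_lines = lines[3:-1]
    if len(coord_lines) != declared:
        raise WrongPointCountError(
            f"{path}: wrong point count: header declares {declared} points "
            f"but file contains {len(coord_lines)} coordinate lines"
        )
    pts = np.empty((declared, 2), dtype=float)
    for i, ln in enumerate(coord_lines):
        tokens = ln.split()
        if len(tokens) != 2:
            raise InvalidCoordinateError(
                f"{path}: line {i + 4}: expected 'x y', got {ln!r}"
            )
        try:
            pts[i] = [float(tokens[0]), float(tokens[1])]
        except ValueError as exc:
            raise InvalidCoordinateError(
                f"{path}: line {i + 4}: non-numeric coordinate in {ln!r}"
            ) from exc
    if not np.all(np.isfinite(pts)):
        raise InvalidCoordinateError(f"{path}: non-finite coordinate value")

    meta = _read_metadata(path)
    return LandmarkConfiguration(points=pts, **meta)


def _read_metadata(path: Path) -> dict:
    """Metadata from sidecar JSON (preferred) or the filename convention."""
    sidecar = path.with_suffix("").with_suffix("")  # strip .pts
    sidecar = path.parent / (path.stem + ".meta.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        return {
            "hip_id": raw.get("hip_id", path.stem),
            "participant_id": raw["participant_id"],
            "side": raw["side"],
            "sex": raw.get("sex"),
        }
    stem = path.stem
    m = re.match(r"^(?P<pid>.+)_(?P<side>left|right)$", stem)
    if m is None:
        raise PointsFileError(
            f"{path}: no sidecar {sidecar.name} and filename does not match "
            "'<participant>_<side>.pts'"
        )
    return {
        "hip_id": stem,
        "participant_id": m.group("pid"),
        "side": m.group("side"),
        "sex": None,
    }


def write_points_file(
    config: LandmarkConfiguration, path: str | Path, sidecar: bool = True
) -> Path:
    """Write a landmark configuration in the ``.pts`` dialect.

    Coordinates are written with 17 significant digits, enough for an exact
    double-precision round trip.  An existing file is
    overwritten (with a log notice); missing parent directories are created.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.exists():
        logger.info("overwriting existing landmark file %s", path)
    lines = ["version: 1", f"n_points: {N_POINTS}", "{"]
    lines += [f"{x:.17g} {y:.17g}" for x, y in config.points]
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        meta = {
            "hip_id": config.hip_id,
            "participant_id": config.participant_id,
            "side": config.side,
            "sex": config.sex,
        }
        (path.parent / (path.stem + ".meta.json")).write_text(
            json.dumps(meta, sort_keys=True, indent=1) + "\n"
        )
    return path


def read_points_dir(directory: str | Path) -> list[LandmarkConfiguration]:
    """Read every ``.pts`` file in a directory, sorted by filename."""
    directory = Path(directory)
    configs = [read_points_file(p) for p in sorted(directory.glob("*.pts"))]
    ids = [c.hip_id for c in configs]
    if len(set(ids)) != len(ids):
        raise PointsFileError(f"{directory}: duplicate hip_id among landmark files")
    return configs


@dataclass
class HipRecord:
    """Clinical covariates and MRI grades for one hip.

    ``cartilage_grades`` are the ten SHOMRI cartilage subregion grades
    (0 no loss, 1 partial-thickness, 2 full-thickness); ``labral_grades``
    the four labral subregion grades (0 normal .. 5 maceration).
    """

    participant_id: str
    side: str
    sex: str
    age: float
    bmi: float
    symptomatic_status: str
    kl_grade: int
    cartilage_grades: tuple[int, ...] = field(default_factory=tuple)
    labral_grades: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ClinicalTableError(f"unknown side {self.side!r}")
        if self.sex not in SEXES:
            raise ClinicalTableError(f"unknown sex {self.sex!r}")
        if self.symptomatic_status not in STATUS_LEVELS:
            raise ClinicalTableError(
                f"unknown status level {self.symptomatic_status!r}; "
                f"expected one of {STATUS_LEVELS}"
            )
        if not np.isfinite(self.age) or not (0 < self.age < 120):
            raise ClinicalTableError(f"age out of range: {self.age}")
        if not np.isfinite(self.bmi) or not (5 < self.bmi < 80):
            raise ClinicalTableError(f"bmi out of range: {self.bmi}")
        self.kl_grade = int(self.kl_grade)
        if not 0 <= self.kl_grade <= 4:
            raise ClinicalTableError(f"kl_grade out of range 0-4: {self.kl_grade}")
        self.cartilage_grades = tuple(int(g) for g in self.cartilage_grades)
        self.labral_grades = tuple(int(g) for g in self.labral_grades)
        if len(self.cartilage_grades) != 10:
            raise ClinicalTableError(
                f"expected 10 cartilage grades, got {len(self.cartilage_grades)}"
            )
        if len(self.labral_grades) != 4:
            raise ClinicalTableError(
                f"expected 4 labral grades, got {len(self.labral_grades)}"
            )
        if any(not 0 <= g <= 2 for g in self.cartilage_grades):
            raise ClinicalTableError(
                f"cartilage grade out of range 0-2: {self.cartilage_grades}"
            )
        if any(not 0 <= g <= 5 for g in self.labral_grades):
            raise ClinicalTableError(
                f"labral grade out of range 0-5: {self.labral_grades}"
            )

    @property
    def hip_id(self) -> str:
        return f"{self.participant_id}_{self.side}"


def records_to_frame(records: Sequence[HipRecord]) -> pd.DataFrame:
    """Tabulate hip records with the canonical CSV column order."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "side": r.side,
            "sex": r.sex,
            "age": r.age,
            "bmi": r.bmi,
            "symptomatic_status": r.symptomatic_status,
            "kl_grade": r.kl_grade,
        }
        row.update(dict(zip(CARTILAGE_COLS, r.cartilage_grades)))
        row.update(dict(zip(LABRAL_COLS, r.labral_grades)))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(HIP_TABLE_COLS))


def frame_to_records(df: pd.DataFrame) -> list[HipRecord]:
    missing = [c for c in HIP_TABLE_COLS if c not in df.columns]
    if missing:
        raise ClinicalTableError(f"missing column(s): {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                HipRecord(
                    participant_id=str(row["participant_id"]),
                    side=str(row["side"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    bmi=float(row["bmi"]),
                    symptomatic_status=str(row["symptomatic_status"]),
                    kl_grade=int(row["kl_grade"]),
                    cartilage_grades=tuple(int(row[c]) for c in CARTILAGE_COLS),
                    labral_grades=tuple(int(row[c]) for c in LABRAL_COLS),
                )
            )
        except ClinicalTableError as exc:
            raise ClinicalTableError(f"row {idx}: {exc}") from exc
    return records


def read_hip_table(path: str | Path) -> list[HipRecord]:
    """Read and validate the clinical CSV; header-only files yield ``[]``."""
    df = pd.read_csv(path)
    return frame_to_records(df)


def write_hip_table(records: Sequence[HipRecord] | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)
    return path


__all__ = [
    "N_POINTS",
    "LandmarkConfiguration",
    "HipRecord",
    "PointsFileError",
    "MalformedHeaderError",
    "WrongPointCountError",
    "InvalidCoordinateError",
    "ClinicalTableError",
    "read_points_file",
    "write_points_file",
    "read_points_dir",
    "read_hip_table",
    "write_hip_table",
    "records_to_frame",
    "frame_to_records",
    "CARTILAGE_COLS",
    "LABRAL_COLS",
    "HIP_TABLE_COLS",
]
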