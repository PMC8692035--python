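"""Reading and writing cohort tables, landmark files and fit-result tables.

All lengths are millimetres, heights metres, weights kilograms, ages years.
No unit conversion happens anywhere in the package; files store the same
units the in-memory records carry.

Landmark files describe, per patient, the 3D positions of the anatomical
boundary of the posterior rectus sheath plane (PRSP): the caudal tip of the
xiphoid process, the cranial tip of the pubic symphysis, and — at a series
of craniocaudal stations roughly 30 mm apart — the linea alba and the left
and right semilunar points.

Coordinate convention (right-handed): x = patient's left (+), y = anterior
(+), z = cranial (+). The origin is arbitrary per patient; every downstream
geometric quantity is rigid-motion invariant.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ValidationError",
    "PatientRecord",
    "Station",
    "LandmarkSet",
    "FitResultRow",
    "read_cohort",
    "write_cohort",
    "read_landmarks",
    "write_landmarks",
    "read_results",
    "write_results",
    "COHORT_COLUMNS",
    "LANDMARK_COLUMNS",
    "RESULT_COLUMNS",
]


class ValidationError(ValueError):
    """Input data violates the documented schema or an invariant."""


_SEXES = ("female", "male")
_SIDES = ("left", "right")
_SHAPES = ("circle", "rectangle", "ellipse", "polygon")

#: Optional anthropometric distance fields of :class:`PatientRecord` (mm).
DISTANCE_FIELDS = (
    "asis_distance",
    "xiphoid_pubis_distance",
    "body_depth",
    "body_width",
    "body_circumference",
)

COHORT_COLUMNS = [
    "patient_id", "sex", "age_years", "height_m", "weight_kg", "bmi",
    "asis_mm", "xiphoid_pubis_mm", "depth_mm", "width_mm", "circumference_mm",
]

LANDMARK_COLUMNS = ["patient_id", "landmark", "station_index", "x_mm", "y_mm", "z_mm"]

RESULT_COLUMNS = [
    "patient_id", "side", "shape", "area_mm2", "slice_index", "params_json",
]


def _fmt(x: float | None) -> str:
    """Full-precision decimal text so that write→read round-trips bitwise."""
    return "" if x is None else repr(float(x))


@dataclass(frozen=True)
class PatientRecord:
    """One participant's demographics and physical-exam distances.

    ``bmi`` is derived as weight/height² when absent but height and weight
    are present. The five distances are the CT-derived features used by the
    screening models; any of them (and height/weight/bmi) may be missing.
    """

    patient_id: str
    sex: str
    age: float
    height: float | None = None
    weight: float | None = None
    bmi: float | None = None
    asis_distance: float | None = None
    xiphoid_pubis_distance: float | None = None
    body_depth: float | None = None
    body_width: float | None = None
    body_circumference: float | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.sex not in _SEXES:
            raise ValidationError(
                f"patient {self.patient_id}: sex must be one of {_SEXES}, got {self.sex!r}")
        if not (self.age >= 0 and math.isfinite(self.age)):
            raise ValidationError(f"patient {self.patient_id}: age must be >= 0")
        for name in ("height", "weight"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(
                    f"patient {self.patient_id}: {name} must be > 0, got {v}")
        if self.bmi is None and self.height is not None and self.weight is not None:
            object.__setattr__(self, "bmi", self.weight / self.height ** 2)
        if self.bmi is not None and not self.bmi > 0:
            raise ValidationError(f"patient {self.patient_id}: bmi must be > 0")
        for name in DISTANCE_FIELDS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(
                    f"patient {self.patient_id}: {name} must be > 0, got {v}")

    @property
    def missing_fields(self) -> tuple[str, ...]:
        """Names of optional screening features that are absent."""
        out = []
        for name in ("bmi",) + DISTANCE_FIELDS:
            if getattr(self, name) is None:
                out.append(name)
        return tuple(out)


@dataclass(frozen=True)
class Station:
    """One craniocaudal measurement level: midline plus both semilunar points."""

    station_index: int
    linea_alba: np.ndarray
    semilunar_left: np.ndarray
    semilunar_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("linea_alba", "semilunar_left", "semilunar_right"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ValidationError(f"station {self.station_index}: {name} must be a 3-vector")
            object.__setattr__(self, name, p)

    def __eq__(self, other: object) -> bool:  # ndarray fields need explicit eq
        if not isinstance(other, Station):
            return NotImplemented
        return (self.station_index == other.station_index
                and np.array_equal(self.linea_alba, other.linea_alba)
                and np.array_equal(self.semilunar_left, other.semilunar_left)
                and np.array_equal(self.semilunar_right, other.semilunar_right))


@dataclass(frozen=True)
class LandmarkSet:
    """All PRSP boundary landmarks of one patient (units mm).

    Invariants: at least 3 stations; station z strictly decreasing
    cranial→caudal; the xiphoid tip cranial to the pubis tip; at every
    station the left semilunar point lies on the +x side of the linea alba
    and the right on the −x side.
    """

    patient_id: str
    xiphoid_tip: np.ndarray
    pubis_tip: np.ndarray
    stations: tuple[Station, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("xiphoid_tip", "pubis_tip"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ValidationError(f"patient {self.patient_id}: {name} must be a 3-vector")
            object.__setattr__(self, name, p)
        object.__setattr__(self, "stations", tuple(self.stations))
        if len(self.stations) < 3:
            raise ValidationError(
                f"patient {self.patient_id}: at least 3 stations required, got {len(self.stations)}")
        z = np.array([s.linea_alba[2] for s in self.stations])
        if not np.all(np.diff(z) < 0):
            raise ValidationError(
                f"patient {self.patient_id}: station craniocaudal coordinates must be "
                "strictly decreasing (cranial -> caudal)")
        if not self.xiphoid_tip[2] > self.pubis_tip[2]:
            raise ValidationError(
                f"patient {self.patient_id}: xiphoid tip must be cranial to pubis tip")
        for s in self.stations:
            if not s.semilunar_left[0] > s.linea_alba[0]:
                raise ValidationError(
                    f"patient {self.patient_id}, station {s.station_index}: "
                    "semilunar_left must lie on the +x side of the linea alba")
            if not s.semilunar_right[0] < s.linea_alba[0]:
                raise ValidationError(
                    f"patient {self.patient_id}, station {s.station_index}: "
                    "semilunar_right must lie on the -x side of the linea alba")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return (self.patient_id == other.patient_id
                and np.array_equal(self.xiphoid_tip, other.xiphoid_tip)
                and np.array_equal(self.pubis_tip, other.pubis_tip)
                and self.stations == other.stations)

    def side_points(self, side: str) -> np.ndarray:
        """Boundary point cloud of one side's PRSP (shared midline included)."""
        if side not in _SIDES:
            raise ValidationError(f"side must be one of {_SIDES}, got {side!r}")
        key = "semilunar_left" if side == "left" else "semilunar_right"
        pts = [self.xiphoid_tip, self.pubis_tip]
        for s in self.stations:
            pts.append(s.linea_alba)
            pts.append(getattr(s, key))
        return np.array(pts, dtype=float)


@dataclass(frozen=True)
class FitResultRow:
    """Serialized best-fit device of one (patient, side, shape)."""

    patient_id: str
    side: str
    shape: str
    area: float
    slice_index: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValidationError(f"side must be one of {_SIDES}, got {self.side!r}")
        if self.shape not in _SHAPES:
            raise ValidationError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if not self.area > 0:
            raise ValidationError(
                f"patient {self.patient_id}: area must be > 0, got {self.area}")
        if self.slice_index < 0:
            raise ValidationError("slice_index must be >= 0")


# ---------------------------------------------------------------------------
# cohort table


def write_cohort(records: list[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for r in records:
            w.writerow([
                r.patient_id, r.sex, _fmt(r.age), _fmt(r.height), _fmt(r.weight),
                _fmt(r.bmi), _fmt(r.asis_distance), _fmt(r.xiphoid_pubis_distance),
                _fmt(r.body_depth), _fmt(r.body_width), _fmt(r.body_circumference),
            ])
    return path


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV; derives BMI where possible, keeps optional gaps."""
    path = Path(path)
    records: list[PatientRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != COHORT_COLUMNS:
            raise ValidationError(
                f"{path}: cohort header mismatch; expected {COHORT_COLUMNS}, got {header}")
        for row in reader:
            if not row:
                continue
            pid = row[0]
            if pid in seen:
                raise ValidationError(f"{path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            vals = [float(v) if v != "" else None for v in row[2:]]
            records.append(PatientRecord(
                patient_id=pid, sex=row[1], age=vals[0], height=vals[1],
                weight=vals[2], bmi=vals[3], asis_distance=vals[4],
                xiphoid_pubis_distance=vals[5], body_depth=vals[6],
                body_width=vals[7], body_circumference=vals[8]))
    return records


# ---------------------------------------------------------------------------
# landmark files

_XP_LANDMARKS = ("xiphoid", "pubis")
_STATION_LANDMARKS = ("linea_alba", "semilunar_left", "semilunar_right")


def write_landmarks(sets: list[LandmarkSet], path: str | Path,
                    schema: str = "csv") -> Path:
    """One row per (patient, station, landmark); xiphoid/pubis use station −1."""
    path = Path(path)
    if schema == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(LANDMARK_COLUMNS)
            for ls in sets:
                for name, p in (("xiphoid", ls.xiphoid_tip), ("pubis", ls.pubis_tip)):
                    w.writerow([ls.patient_id, name, -1,
                                _fmt(p[0]), _fmt(p[1]), _fmt(p[2])])
                for s in ls.stations:
                    for name in _STATION_LANDMARKS:
                        p = getattr(s, name)
                        w.writerow([ls.patient_id, name, s.station_index,
                                    _fmt(p[0]), _fmt(p[1]), _fmt(p[2])])
    elif schema == "json":
        doc = []
        for ls in sets:
            doc.append({
                "patient_id": ls.patient_id,
                "xiphoid_tip": [float(v) for v in ls.xiphoid_tip],
                "pubis_tip": [float(v) for v in ls.pubis_tip],
                "stations": [
                    {"station_index": s.station_index,
                     "linea_alba": [float(v) for v in s.linea_alba],
                     "semilunar_left": [float(v) for v in s.semilunar_left],
                     "semilunar_right": [float(v) for v in s.semilunar_right]}
                    for s in ls.stations],
            })
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown landmark schema {schema!r}")
    return path


def _landmarks_from_rows(pid: str, rows: list[tuple[str, int, np.ndarray]]) -> LandmarkSet:
    singles: dict[str, np.ndarray] = {}
    stations: dict[int, dict[str, np.ndarray]] = {}
    for name, idx, p in rows:
        if name in _XP_LANDMARKS:
            if name in singles:
                raise ValidationError(f"patient {pid}: duplicate landmark {name!r}")
            singles[name] = p
        elif name in _STATION_LANDMARKS:
            st = stations.setdefault(idx, {})
            if name in st:
                raise ValidationError(
                    f"patient {pid}: duplicate landmark {name!r} at station {idx}")
            st[name] = p
        else:
            raise ValidationError(f"patient {pid}: unknown landmark {name!r}")
    for name in _XP_LANDMARKS:
        if name not in singles:
            raise ValidationError(f"patient {pid}: missing mandatory landmark {name!r}")
    built = []
    for idx in sorted(stations):
        st = stations[idx]
        for name in _STATION_LANDMARKS:
            if name not in st:
                raise ValidationError(
                    f"patient {pid}: missing landmark {name!r} at station {idx}")
        built.append(Station(idx, st["linea_alba"], st["semilunar_left"],
                             st["semilunar_right"]))
    # stations sorted cranial -> caudal (descending z); validation re-checks
    built.sort(key=lambda s: -s.linea_alba[2])
    return LandmarkSet(pid, singles["xiphoid"], singles["pubis"], tuple(built))


def read_landmarks(path: str | Path, schema: str = "csv") -> list[LandmarkSet]:
    path = Path(path)
    per_patient: dict[str, list[tuple[str, int, np.ndarray]]] = {}
    order: list[str] = []
    if schema == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != LANDMARK_COLUMNS:
                raise ValidationError(
                    f"{path}: landmark header mismatch; expected {LANDMARK_COLUMNS}")
            for row in reader:
                if not row:
                    continue
                pid, name, idx = row[0], row[1], int(row[2])
                p = np.array([float(row[3]), float(row[4]), float(row[5])])
                if pid not in per_patient:
                    per_patient[pid] = []
                    order.append(pid)
                per_patient[pid].append((name, idx, p))
    elif schema == "json":
        with open(path) as fh:
            doc = json.load(fh)
        out = []
        seen: set[str] = set()
        for entry in doc:
            pid = entry["patient_id"]
            if pid in seen:
                raise ValidationError(f"{path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            out.append(LandmarkSet(
                pid, np.array(entry["xiphoid_tip"], float),
                np.array(entry["pubis_tip"], float),
                tuple(Station(s["station_index"], np.array(s["linea_alba"], float),
                              np.array(s["semilunar_left"], float),
                              np.array(s["semilunar_right"], float))
                      for s in entry["stations"])))
        return out
    else:
        raise ValidationError(f"unknown landmark schema {schema!r}")
    return [_landmarks_from_rows(pid, per_patient[pid]) for pid in order]


# ---------------------------------------------------------------------------
# fit-result tables


def write_results(rows: list[FitResultRow], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for r in rows:
            w.writerow([r.patient_id, r.side, r.shape, _fmt(r.area),
                        r.slice_index,
                        json.dumps(r.params, sort_keys=True)])
    return path


def read_results(path: str | Path) -> list[FitResultRow]:
    path = Path(path)
    rows: list[FitResultRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != RESULT_COLUMNS:
            raise ValidationError(f"{path}: results header mismatch")
        for row in reader:
            if not row:
                continue
            rows.append(FitResultRow(
                patient_id=row[0], side=row[1], shape=row[2],
                area=float(row[3]), slice_index=int(row[4]),
                params=json.loads(row[5])))
    return rows
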