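"""Reading and writing landmark and metadata files.

Two dialects carry identical content:

* **JSON** — one document per patient-timepoint::

      {
        "schema_version": 1,
        "patient_id": "P01",
        "timepoint": "pre",
        "paralyzed_side": "left",
        "conditions": {
          "REST": {
            "iris_center_left": [412.0, 305.5],
            ...,
            "lower_lip_vermilion": [[380.0, 520.1], ...]
          },
          ...
        }
      }

* **long CSV** — columns ``patient_id, timepoint, condition, landmark, x, y``
  with vermilion vertices serialized as ``lower_lip_vermilion.<index>``.

All coordinates are 0-based pixel floats.  Unknown fields are ignored with
a logged warning.  Writers emit byte-stable output for identical input.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from facesym.errors import SchemaError
from facesym.landmarks import (
    AnatomicalSide,
    AnnotatedFace,
    Condition,
    EyeChoice,
    LandmarkSet,
    PatientMeta,
    Point2D,
    POINT_LANDMARKS,
    Timepoint,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

META_COLUMNS = [
    "id",
    "age",
    "gender",
    "cause",
    "paralysis_duration",
    "paralyzed_side",
    "preop_fngs_grade",
    "time_to_first_contraction",
    "followup",
]


def _placeholder_meta(patient_id: str, paralyzed_side: str) -> PatientMeta:
    """Minimal metadata when a landmark file is read without its cohort table."""
    return PatientMeta(
        id=patient_id,
        age=40.0,
        gender="female",
        cause="other",
        paralysis_duration=12.0,
        paralyzed_side=AnatomicalSide(paralyzed_side),
        preop_fngs_grade=5,
    )


# ---------------------------------------------------------------- JSON


def face_to_json_dict(face: AnnotatedFace) -> dict:
    conditions = {}
    for cond in sorted(face.sets, key=lambda c: c.value):
        lset = face.sets[cond]
        doc: dict = {}
        for name in POINT_LANDMARKS:
            p = lset.points.get(name)
            if p is not None:
                doc[name] = [p.x, p.y]
        doc["lower_lip_vermilion"] = [[p.x, p.y] for p in lset.lower_lip_vermilion]
        conditions[cond.value] = doc
    return {
        "schema_version": SCHEMA_VERSION,
        "patient_id": face.meta.id,
        "timepoint": face.timepoint.value,
        "paralyzed_side": face.meta.paralyzed_side.value,
        "conditions": conditions,
    }


def write_landmarks_json(face: AnnotatedFace, path: str | Path) -> None:
    doc = face_to_json_dict(face)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _landmark_set_from_dict(condition: str, doc: dict) -> LandmarkSet:
    points = {}
    vermilion = []
    for key, value in doc.items():
        if key == "lower_lip_vermilion":
            try:
                vermilion = [Point2D(float(x), float(y)) for x, y in value]
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"malformed vermilion polyline in condition {condition}: {exc}"
                ) from exc
        elif key in POINT_LANDMARKS:
            try:
                x, y = value
                points[key] = Point2D(float(x), float(y))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"malformed coordinates for {key} in {condition}: {value!r}"
                ) from exc
        else:
            logger.warning("ignoring unknown landmark field %r in %s", key, condition)
    return LandmarkSet(
        condition=Condition(condition), points=points, lower_lip_vermilion=vermilion
    )


def read_landmarks_json(
    path: str | Path, meta: Optional[PatientMeta] = None
) -> AnnotatedFace:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    known = {"schema_version", "patient_id", "timepoint", "paralyzed_side", "conditions"}
    for key in doc:
        if key not in known:
            logger.warning("ignoring unknown top-level field %r in %s", key, path)
    for req in ("patient_id", "timepoint", "conditions"):
        if req not in doc:
            raise SchemaError(f"{path}: missing required field '{req}'")
    sets = [
        _landmark_set_from_dict(cond, cdoc) for cond, cdoc in doc["conditions"].items()
    ]
    if meta is None:
        meta = _placeholder_meta(doc["patient_id"], doc.get("paralyzed_side", "left"))
    return AnnotatedFace.from_sets(meta, Timepoint(doc["timepoint"]), sets)


# ---------------------------------------------------------------- CSV


def face_to_rows(face: AnnotatedFace) -> list[tuple]:
    rows = []
    for cond in sorted(face.sets, key=lambda c: c.value):
        lset = face.sets[cond]
        for name in POINT_LANDMARKS:
            p = lset.points.get(name)
            if p is not None:
                rows.append((face.meta.id, face.timepoint.value, cond.value, name, p.x, p.y))
        for i, p in enumerate(lset.lower_lip_vermilion):
            rows.append(
                (
                    face.meta.id,
                    face.timepoint.value,
                    cond.value,
                    f"lower_lip_vermilion.{i}",
                    p.x,
                    p.y,
                )
            )
    return rows


def write_landmarks_csv(face: AnnotatedFace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "timepoint", "condition", "landmark", "x", "y"])
        writer.writerows(face_to_rows(face))


def read_landmarks_csv(
    path: str | Path,
    meta: Optional[PatientMeta] = None,
    paralyzed_side: str = "left",
) -> AnnotatedFace:
    df = pd.read_csv(path)
    required = {"patient_id", "timepoint", "condition", "landmark", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing CSV columns {sorted(missing)}")
    ids = df["patient_id"].unique()
    tps = df["timepoint"].unique()
    if len(ids) != 1 or len(tps) != 1:
        raise SchemaError(
            f"{path}: expected a single patient-timepoint, found ids={ids}, timepoints={tps}"
        )
    sets = []
    for cond, grp in df.groupby("condition", sort=True):
        points = {}
        verm: list[tuple[int, Point2D]] = []
        for row_i, row in grp.iterrows():
            name = str(row["landmark"])
            try:
                p = Point2D(float(row["x"]), float(row["y"]))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: malformed coordinates at row {row_i} ({name})"
                ) from exc
            if name.startswith("lower_lip_vermilion."):
                verm.append((int(name.rsplit(".", 1)[1]), p))
            elif name in POINT_LANDMARKS:
                points[name] = p
            else:
                logger.warning("ignoring unknown landmark %r in %s", name, path)
        verm.sort(key=lambda t: t[0])
        sets.append(
            LandmarkSet(
                condition=Condition(cond),
                points=points,
                lower_lip_vermilion=[p for _, p in verm],
            )
        )
    if meta is None:
        meta = _placeholder_meta(str(ids[0]), paralyzed_side)
    return AnnotatedFace.from_sets(meta, Timepoint(tps[0]), sets)


def read_landmarks(
    path: str | Path,
    schema: Optional[str] = None,
    meta: Optional[PatientMeta] = None,
) -> AnnotatedFace:
    """Read a landmark file; the dialect is inferred from the suffix unless given."""
    path = Path(path)
    if schema is None:
        schema = "csv" if path.suffix.lower() == ".csv" else "json"
    if schema == "json":
        return read_landmarks_json(path, meta)
    if schema == "csv":
        return read_landmarks_csv(path, meta)
    raise SchemaError(f"unknown landmark schema dialect {schema!r}")


# ---------------------------------------------------------------- metadata


def write_meta_csv(metas: list[PatientMeta], path: str | Path) -> None:
    records = [m.model_dump() for m in metas]
    for r in records:
        r["paralyzed_side"] = (
            r["paralyzed_side"].value
            if hasattr(r["paralyzed_side"], "value")
            else r["paralyzed_side"]
        )
    pd.DataFrame.from_records(records, columns=META_COLUMNS).to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> dict[str, PatientMeta]:
    df = pd.read_csv(path)
    missing = set(META_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing metadata columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        d = row.to_dict()
        for opt in ("time_to_first_contraction", "followup"):
            if opt in d and pd.isna(d[opt]):
                d[opt] = None
        d["id"] = str(d["id"])
        out[d["id"]] = PatientMeta(**d)
    return out
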