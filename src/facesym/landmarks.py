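"""Landmark domain types, pixel→mm calibration, and the face coordinate frame.

Raw coordinates follow the image raster convention: x grows rightward,
y grows *downward*, in pixels.  Every metric downstream is expressed in a
face-centric frame whose x-axis runs along the inter-iris direction toward
the healthy side and whose y-axis points superiorly (so vertical
excursions are positive upward, as a clinician reads them).  Pixel
distances are converted to millimetres with the corneal horizontal
white-to-white diameter, standardized at 11.576 mm, as the in-image ruler.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from facesym.errors import GeometryError, MissingLandmarkError

#: Standardized horizontal corneal white-to-white diameter in millimetres.
WHITE_TO_WHITE_MM = 11.576


class Condition(str, enum.Enum):
    """Task conditions captured during the photographic protocol."""

    REST = "REST"
    BROW_RAISE = "BROW_RAISE"
    EYE_CLOSURE = "EYE_CLOSURE"
    SNARL = "SNARL"
    SMILE = "SMILE"


class Timepoint(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class AnatomicalSide(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def other(self) -> "AnatomicalSide":
        return AnatomicalSide.RIGHT if self is AnatomicalSide.LEFT else AnatomicalSide.LEFT


class FunctionalSide(str, enum.Enum):
    """Side labels relative to the paralysis, used by all metrics."""

    HEALTHY = "healthy"
    PARALYTIC = "paralytic"


class EyeChoice(str, enum.Enum):
    """Which eye anchors the white-to-white calibration."""

    HEALTHY = "healthy"
    PARALYTIC = "paralytic"
    MEAN = "mean"


@dataclass(frozen=True)
class Point2D:
    """An image-space point in pixels (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


#: Landmarks every set must carry (the calibration anchors).
ALWAYS_REQUIRED = (
    "iris_center_left",
    "iris_center_right",
    "limbus_medial_left",
    "limbus_lateral_left",
    "limbus_medial_right",
    "limbus_lateral_right",
)

#: All point-valued landmark names, in canonical serialization order.
POINT_LANDMARKS = ALWAYS_REQUIRED + (
    "medial_canthus_left",
    "medial_canthus_right",
    "oral_commissure_left",
    "oral_commissure_right",
    "philtrum",
    "eyelid_upper_left",
    "eyelid_lower_left",
    "eyelid_upper_right",
    "eyelid_lower_right",
)


@dataclass
class LandmarkSet:
    """All annotated landmarks for one task condition.

    ``left``/``right`` suffixes are anatomical labels, independent of which
    side is paralyzed.  Eyelid points are taken on the vertical through the
    ipsilateral iris center; limbus points are the horizontal corneal
    extremes.  ``lower_lip_vermilion`` is an ordered polyline spanning
    horizontally across both oral commissures.
    """

    condition: Condition
    points: dict[str, Point2D] = field(default_factory=dict)
    lower_lip_vermilion: list[Point2D] = field(default_factory=list)

    def __post_init__(self):
        self.condition = Condition(self.condition)
        for name in self.points:
            if name not in POINT_LANDMARKS:
                raise ValueError(f"unknown landmark name '{name}'")
        for name in ALWAYS_REQUIRED:
            if name not in self.points:
                raise MissingLandmarkError(name, self.condition.value)

    def require(self, name: str) -> Point2D:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name, self.condition.value) from None

    def get(self, name: str) -> Optional[Point2D]:
        return self.points.get(name)

    def iris_center(self, side: AnatomicalSide) -> Point2D:
        return self.require(f"iris_center_{side.value}")


class PatientMeta(BaseModel):
    """Demographic and clinical covariates for one patient."""

    id: str
    age: float = Field(gt=0)
    gender: str  # "female" | "male"
    cause: str  # tumor | bell_palsy | trauma | infection | other
    paralysis_duration: float = Field(gt=0, description="months")
    paralyzed_side: AnatomicalSide
    preop_fngs_grade: int = Field(ge=1, le=6)
    time_to_first_contraction: Optional[float] = Field(default=None, ge=0)
    followup: Optional[float] = Field(default=None, gt=0)

    @field_validator("gender")
    @classmethod
    def _gender(cls, v: str) -> str:
        if v not in {"female", "male"}:
            raise ValueError(f"gender must be 'female' or 'male', got {v!r}")
        return v

    @field_validator("cause")
    @classmethod
    def _cause(cls, v: str) -> str:
        allowed = {"tumor", "bell_palsy", "trauma", "infection", "other"}
        if v not in allowed:
            raise ValueError(f"cause must be one of {sorted(allowed)}, got {v!r}")
        return v

    @property
    def healthy_side(self) -> AnatomicalSide:
        return self.paralyzed_side.other

    def anatomical(self, side: FunctionalSide) -> AnatomicalSide:
        """Map a healthy/paralytic label to the anatomical side."""
        if side is FunctionalSide.PARALYTIC:
            return self.paralyzed_side
        return self.healthy_side


@dataclass(frozen=True)
class CalibrationInfo:
    """Pixel→millimetre scale derived from the white-to-white diameter."""

    mm_per_pixel: float
    source_eye: EyeChoice
    wtw_pixels: float

    def __post_init__(self):
        if self.wtw_pixels <= 0 or self.mm_per_pixel <= 0:
            raise GeometryError(
                f"degenerate white-to-white extent: {self.wtw_pixels} px"
            )

    def to_mm(self, pixels: float) -> float:
        return pixels * self.mm_per_pixel


@dataclass(frozen=True)
class FaceFrame:
    """Face-centric orthonormal frame in image space.

    ``origin`` is the reference point: the intersection of the facial
    central line (perpendicular bisector of the inter-iris segment) with
    the vermilion margin of the lower lip.  ``x_axis`` runs along the
    inter-iris direction toward the healthy side; ``y_axis`` is
    perpendicular and points superiorly.
    """

    origin: Point2D
    x_axis: np.ndarray
    y_axis: np.ndarray

    def to_face_px(self, p: Point2D) -> tuple[float, float]:
        d = p.as_array() - self.origin.as_array()
        return float(d @ self.x_axis), float(d @ self.y_axis)


def wtw_pixels_of_eye(lset: LandmarkSet, side: AnatomicalSide) -> float:
    medial = lset.require(f"limbus_medial_{side.value}")
    lateral = lset.require(f"limbus_lateral_{side.value}")
    return medial.distance_to(lateral)


def compute_calibration(
    lset: LandmarkSet,
    source_eye: EyeChoice | str = EyeChoice.HEALTHY,
    paralyzed_side: AnatomicalSide | str = AnatomicalSide.LEFT,
) -> CalibrationInfo:
    """Derive the mm-per-pixel scale from the corneal white-to-white extent.

    ``source_eye='mean'`` averages the two eyes' pixel extents before
    dividing into the 11.576 mm standard, so the calibration identity
    ``mm_per_pixel * wtw_pixels == 11.576`` holds for the stored extent.
    """
    source_eye = EyeChoice(source_eye)
    paralyzed_side = AnatomicalSide(paralyzed_side)
    if source_eye is EyeChoice.MEAN:
        wtw = 0.5 * (
            wtw_pixels_of_eye(lset, AnatomicalSide.LEFT)
            + wtw_pixels_of_eye(lset, AnatomicalSide.RIGHT)
        )
    else:
        anatomical = (
            paralyzed_side
            if source_eye is EyeChoice.PARALYTIC
            else paralyzed_side.other
        )
        wtw = wtw_pixels_of_eye(lset, anatomical)
    if wtw <= 0:
        raise GeometryError("white-to-white extent is zero: coincident limbus points")
    return CalibrationInfo(
        mm_per_pixel=WHITE_TO_WHITE_MM / wtw, source_eye=source_eye, wtw_pixels=wtw
    )


def _bisector_polyline_intersections(
    mid: np.ndarray, normal: np.ndarray, polyline: list[Point2D]
) -> list[np.ndarray]:
    """Intersections of the line {p: (p-mid)·normal = 0} with a polyline."""
    hits: list[np.ndarray] = []
    pts = [p.as_array() for p in polyline]
    for a, b in zip(pts[:-1], pts[1:]):
        da = float((a - mid) @ normal)
        db = float((b - mid) @ normal)
        if da == 0.0:
            hits.append(a)
            continue
        if da * db < 0.0:
            t = da / (da - db)
            hits.append(a + t * (b - a))
    if pts and float((pts[-1] - mid) @ normal) == 0.0:
        hits.append(pts[-1])
    return hits


def build_face_frame(
    lset: LandmarkSet,
    healthy_side: AnatomicalSide | str = AnatomicalSide.RIGHT,
) -> FaceFrame:
    """Construct the face frame from iris centers and the lower-lip vermilion.

    The central line of the face is the perpendicular bisector of the
    segment joining the two iris centers; its intersection with the
    vermilion polyline is the reference point (frame origin).  If the
    polyline crosses the central line more than once, the intersection
    nearest the inter-commissure midpoint is chosen.
    """
    healthy_side = AnatomicalSide(healthy_side)
    iris_l = lset.iris_center(AnatomicalSide.LEFT).as_array()
    iris_r = lset.iris_center(AnatomicalSide.RIGHT).as_array()
    inter = iris_r - iris_l
    norm = float(np.linalg.norm(inter))
    if norm < 1e-12:
        raise GeometryError("iris centers coincide; cannot orient the face")
    if not lset.lower_lip_vermilion or len(lset.lower_lip_vermilion) < 2:
        raise MissingLandmarkError("lower_lip_vermilion", lset.condition.value)

    mid = 0.5 * (iris_l + iris_r)
    unit_inter = inter / norm  # points from left iris to right iris
    hits = _bisector_polyline_intersections(mid, unit_inter, lset.lower_lip_vermilion)
    if not hits:
        raise GeometryError(
            "central line does not intersect the lower-lip vermilion polyline"
        )
    if len(hits) > 1:
        ca = lset.require("oral_commissure_left").as_array()
        cb = lset.require("oral_commissure_right").as_array()
        anchor = 0.5 * (ca + cb)
        hits.sort(key=lambda h: float(np.linalg.norm(h - anchor)))
    origin = hits[0]

    x_axis = unit_inter if healthy_side is AnatomicalSide.RIGHT else -unit_inter
    # The central line is perpendicular to x_axis and passes through both the
    # inter-iris midpoint and the origin, so mid - origin is the superior
    # direction; orthonormalize against x_axis for numerical hygiene.
    up = mid - origin
    up = up - (up @ x_axis) * x_axis
    nu = float(np.linalg.norm(up))
    if nu < 1e-12:
        raise GeometryError("reference point coincides with the inter-iris midpoint")
    y_axis = up / nu
    return FaceFrame(
        origin=Point2D(float(origin[0]), float(origin[1])),
        x_axis=x_axis,
        y_axis=y_axis,
    )


def to_face_mm(
    p: Point2D, frame: FaceFrame, calib: CalibrationInfo
) -> tuple[float, float]:
    """Express an image point in face-frame millimetres.

    Returns ``(u, v)``: u is the lateral coordinate (positive toward the
    healthy side), v the vertical coordinate (positive superiorly).
    """
    u_px, v_px = frame.to_face_px(p)
    return calib.to_mm(u_px), calib.to_mm(v_px)


def from_face_mm(
    uv: tuple[float, float], frame: FaceFrame, calib: CalibrationInfo
) -> Point2D:
    """Inverse of :func:`to_face_mm` (used for round-trip checks)."""
    u_px = uv[0] / calib.mm_per_pixel
    v_px = uv[1] / calib.mm_per_pixel
    xy = frame.origin.as_array() + u_px * frame.x_axis + v_px * frame.y_axis
    return Point2D(float(xy[0]), float(xy[1]))


@dataclass
class AnnotatedFace:
    """Calibrated landmark sets for one patient at one timepoint."""

    meta: PatientMeta
    timepoint: Timepoint
    sets: dict[Condition, LandmarkSet]
    calibration: CalibrationInfo
    frame: FaceFrame

    def __post_init__(self):
        self.timepoint = Timepoint(self.timepoint)
        self.sets = {Condition(k): v for k, v in self.sets.items()}
        if Condition.REST not in self.sets:
            raise MissingLandmarkError("REST landmark set", "any")

    @classmethod
    def from_sets(
        cls,
        meta: PatientMeta,
        timepoint: Timepoint | str,
        sets: Iterable[LandmarkSet] | dict[Condition, LandmarkSet],
        source_eye: EyeChoice | str = EyeChoice.HEALTHY,
    ) -> "AnnotatedFace":
        """Build a face, deriving calibration and frame from the REST set.

        One calibration is shared by all of the timepoint's conditions
        (photos from a session share scale).
        """
        if not isinstance(sets, dict):
            sets = {s.condition: s for s in sets}
        sets = {Condition(k): v for k, v in sets.items()}
        if Condition.REST not in sets:
            raise MissingLandmarkError("REST landmark set", "any")
        rest = sets[Condition.REST]
        calib = compute_calibration(rest, source_eye, meta.paralyzed_side)
        frame = build_face_frame(rest, meta.healthy_side)
        return cls(
            meta=meta,
            timepoint=Timepoint(timepoint),
            sets=sets,
            calibration=calib,
            frame=frame,
        )

    def set_for(self, condition: Condition | str) -> LandmarkSet:
        condition = Condition(condition)
        try:
            return self.sets[condition]
        except KeyError:
            raise MissingLandmarkError(
                "landmark set", condition.value
            ) from None

    def landmark_mm(
        self, condition: Condition | str, name: str
    ) -> tuple[float, float]:
        """Face-frame (u, v) millimetre coordinates of a named landmark."""
        p = self.set_for(condition).require(name)
        return to_face_mm(p, self.frame, self.calibration)

    def side_landmark(
        self, condition: Condition | str, stem: str, side: FunctionalSide | str
    ) -> Point2D:
        """Fetch e.g. the paralytic-side oral commissure for a condition."""
        side = FunctionalSide(side)
        anatomical = self.meta.anatomical(side)
        return self.set_for(condition).require(f"{stem}_{anatomical.value}")
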