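"""Quantitative facial-symmetry indices measured in the calibrated face frame.

Conventions
-----------
All quantities are millimetres or degrees.  For the oral commissure on a
given side, ``f`` denotes its horizontal distance from the facial central
line and ``g`` its vertical offset from the reference point (superior
positive); primed symbols conventionally refer to the paralytic side.
The philtrum deviation is signed, positive toward the healthy side —
the direction paralysis drags it.

The *smile excursion* of a commissure is the change, from repose to
smile, in the distance from the reference point to that commissure.  The
*static* and *dynamic* excursions are the reference-point distances within
the REST and SMILE conditions respectively; the three terms are kept as
separate operations because the underlying clinical usage overloads the
word "excursion".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from facesym.errors import MissingLandmarkError
from facesym.landmarks import (
    AnnotatedFace,
    Condition,
    FunctionalSide,
    to_face_mm,
)

#: Minimal post-operative smile excursion (mm) for a good reanimation.
GOOD_REANIMATION_THRESHOLD_MM = 3.0


@dataclass(frozen=True)
class CommissureComponents:
    """Face-frame components of one oral commissure (mm)."""

    f: float  # horizontal distance from the central line, >= 0
    g: float  # vertical offset from the reference point, superior positive
    side: FunctionalSide
    condition: Condition


@dataclass(frozen=True)
class SmileExcursion:
    """Rest→smile change of a commissure's position (mm)."""

    dh: float  # change in f
    dv: float  # change in g
    overall: float  # change in distance from the reference point


def _canthus_commissure_mm(face: AnnotatedFace, side: FunctionalSide, condition) -> float:
    canthus = face.side_landmark(condition, "medial_canthus", side)
    commissure = face.side_landmark(condition, "oral_commissure", side)
    return face.calibration.to_mm(canthus.distance_to(commissure))


def facial_asymmetry_index(face: AnnotatedFace, condition=Condition.REST) -> float:
    """Absolute between-side difference of the medial-canthus → ipsilateral
    oral-commissure distance, in mm.  Lower is more symmetric."""
    healthy = _canthus_commissure_mm(face, FunctionalSide.HEALTHY, condition)
    paralytic = _canthus_commissure_mm(face, FunctionalSide.PARALYTIC, condition)
    return abs(paralytic - healthy)


def palpebral_fissure_width(
    face: AnnotatedFace, side: FunctionalSide | str, condition=Condition.REST
) -> float:
    """Eyelid aperture (mm) on the vertical through the iris center; 0 = full closure."""
    upper = face.side_landmark(condition, "eyelid_upper", side)
    lower = face.side_landmark(condition, "eyelid_lower", side)
    return face.calibration.to_mm(upper.distance_to(lower))


def philtrum_deviation(face: AnnotatedFace, condition=Condition.REST) -> float:
    """Signed perpendicular distance (mm) of the philtrum from the facial
    central line, positive toward the healthy side."""
    p = face.set_for(condition).require("philtrum")
    u, _ = to_face_mm(p, face.frame, face.calibration)
    return u


def commissure_components(
    face: AnnotatedFace, side: FunctionalSide | str, condition=Condition.REST
) -> CommissureComponents:
    side = FunctionalSide(side)
    condition = Condition(condition)
    p = face.side_landmark(condition, "oral_commissure", side)
    u, v = to_face_mm(p, face.frame, face.calibration)
    return CommissureComponents(f=abs(u), g=v, side=side, condition=condition)


def commissure_excursion(
    face: AnnotatedFace, side: FunctionalSide | str, condition=Condition.REST
) -> tuple[float, float, float]:
    """(f, g, overall) of a commissure within one condition: the horizontal
    and vertical components and the straight-line distance from the
    reference point (mm).  REST gives the static, SMILE the dynamic values."""
    c = commissure_components(face, side, condition)
    return c.f, c.g, math.hypot(c.f, c.g)


def smile_excursion(face: AnnotatedFace, side: FunctionalSide | str) -> SmileExcursion:
    """Change from repose to smile in the reference-point → commissure
    geometry for one side, at a single timepoint."""
    f0, g0, d0 = commissure_excursion(face, side, Condition.REST)
    f1, g1, d1 = commissure_excursion(face, side, Condition.SMILE)
    return SmileExcursion(dh=f1 - f0, dv=g1 - g0, overall=d1 - d0)


def adjusted_horizontal(
    face: AnnotatedFace, side: FunctionalSide | str, condition=Condition.REST
) -> float:
    """Horizontal commissure distance (mm) measured from the philtrum's
    vertical rather than the central line.

    A philtrum displaced toward the healthy side therefore shortens the
    healthy-side distance and lengthens the paralytic one, removing the
    midline shift from the between-side comparison.
    """
    commissure = face.side_landmark(condition, "oral_commissure", side)
    u_c, _ = to_face_mm(commissure, face.frame, face.calibration)
    dev = philtrum_deviation(face, condition)
    return abs(u_c - dev)


def commissure_angle(
    face: AnnotatedFace, side: FunctionalSide | str, condition=Condition.REST
) -> float:
    """Angle (degrees) of the commissure above the horizontal through the
    reference point: arctan(g / f)."""
    c = commissure_components(face, side, condition)
    if c.f == 0.0:
        warnings.warn(
            "commissure lies on the central line; angle saturates at ±90°",
            stacklevel=2,
        )
        return math.copysign(90.0, c.g)
    return math.degrees(math.atan(c.g / c.f))


def bilateral_slope_angle(face: AnnotatedFace, condition=Condition.REST) -> float:
    """Slope angle (degrees) of the line joining the two commissures:
    arctan((g − g′) / (f + f′)), healthy side unprimed.  Positive when the
    healthy commissure sits higher."""
    h = commissure_components(face, FunctionalSide.HEALTHY, condition)
    p = commissure_components(face, FunctionalSide.PARALYTIC, condition)
    denom = h.f + p.f
    if denom == 0.0:
        raise MissingLandmarkError("oral_commissure (zero bilateral span)", condition)
    return math.degrees(math.atan((h.g - p.g) / denom))


def classify_reanimation(overall_excursion_mm: float) -> str:
    """Classify a post-operative paralytic-side smile excursion.

    Excursions below the 3.0 mm minimum are 'poor'; 3.0 mm and above,
    'good' (the threshold is the minimal excursion *for* good reanimation,
    so the boundary itself classifies as good).
    """
    return "poor" if overall_excursion_mm < GOOD_REANIMATION_THRESHOLD_MM else "good"


# ---------------------------------------------------------------- aggregates

_SIDES = (FunctionalSide.HEALTHY, FunctionalSide.PARALYTIC)


@dataclass
class SymmetryMetrics:
    """Every symmetry index for one patient-timepoint.

    Per-condition quantities are keyed by condition value; per-side
    quantities by 'healthy'/'paralytic'.  Conditions absent from the
    underlying face are simply absent from the dicts.
    """

    patient_id: str
    timepoint: str
    fai_rest: Optional[float] = None
    fai_smile: Optional[float] = None
    palpebral_width: dict = field(default_factory=dict)  # (side, condition) -> mm
    philtrum_dev: dict = field(default_factory=dict)  # condition -> signed mm
    components: dict = field(default_factory=dict)  # (side, condition) -> (f, g)
    static_excursion: dict = field(default_factory=dict)  # side -> (f, g, overall)
    dynamic_excursion: dict = field(default_factory=dict)  # side -> (f, g, overall)
    smile_excursion: dict = field(default_factory=dict)  # side -> SmileExcursion
    adjusted_horizontal: dict = field(default_factory=dict)  # (side, condition) -> mm
    commissure_angle: dict = field(default_factory=dict)  # (side, condition) -> deg
    slope_angle: dict = field(default_factory=dict)  # condition -> deg
    reanimation_class: Optional[str] = None

    def to_row(self) -> dict:
        """Flatten to a stable, CSV-friendly column → value mapping."""
        row: dict = {
            "patient_id": self.patient_id,
            "timepoint": self.timepoint,
            "fai_rest": self.fai_rest,
            "fai_smile": self.fai_smile,
        }
        for cond in Condition:
            row[f"philtrum_dev_{cond.value}"] = self.philtrum_dev.get(cond.value)
            row[f"slope_angle_{cond.value}"] = self.slope_angle.get(cond.value)
            for side in _SIDES:
                key = (side.value, cond.value)
                row[f"palpebral_{side.value}_{cond.value}"] = self.palpebral_width.get(key)
                row[f"adj_horizontal_{side.value}_{cond.value}"] = (
                    self.adjusted_horizontal.get(key)
                )
                row[f"angle_{side.value}_{cond.value}"] = self.commissure_angle.get(key)
        for side in _SIDES:
            for label, store in (
                ("static", self.static_excursion),
                ("dynamic", self.dynamic_excursion),
            ):
                fgo = store.get(side.value)
                for i, comp in enumerate(("f", "g", "overall")):
                    row[f"{label}_excursion_{comp}_{side.value}"] = (
                        fgo[i] if fgo is not None else None
                    )
            exc = self.smile_excursion.get(side.value)
            row[f"smile_excursion_dh_{side.value}"] = exc.dh if exc else None
            row[f"smile_excursion_dv_{side.value}"] = exc.dv if exc else None
            row[f"smile_excursion_overall_{side.value}"] = exc.overall if exc else None
        row["reanimation_class"] = self.reanimation_class
        return row


def measure_face(face: AnnotatedFace) -> SymmetryMetrics:
    """Compute every symmetry index available from the face's conditions."""
    m = SymmetryMetrics(patient_id=face.meta.id, timepoint=face.timepoint.value)
    conditions = set(face.sets)

    m.fai_rest = facial_asymmetry_index(face, Condition.REST)
    if Condition.SMILE in conditions:
        m.fai_smile = facial_asymmetry_index(face, Condition.SMILE)

    for cond in conditions:
        cv = cond.value
        lset = face.sets[cond]
        if lset.get("philtrum") is not None:
            m.philtrum_dev[cv] = philtrum_deviation(face, cond)
        has_commissures = (
            lset.get("oral_commissure_left") is not None
            and lset.get("oral_commissure_right") is not None
        )
        if has_commissures:
            m.slope_angle[cv] = bilateral_slope_angle(face, cond)
        for side in _SIDES:
            key = (side.value, cv)
            anat = face.meta.anatomical(side).value
            if (
                lset.get(f"eyelid_upper_{anat}") is not None
                and lset.get(f"eyelid_lower_{anat}") is not None
            ):
                m.palpebral_width[key] = palpebral_fissure_width(face, side, cond)
            if lset.get(f"oral_commissure_{anat}") is not None:
                c = commissure_components(face, side, cond)
                m.components[key] = (c.f, c.g)
                m.commissure_angle[key] = commissure_angle(face, side, cond)
                if lset.get("philtrum") is not None:
                    m.adjusted_horizontal[key] = adjusted_horizontal(face, side, cond)

    for side in _SIDES:
        m.static_excursion[side.value] = commissure_excursion(face, side, Condition.REST)
        if Condition.SMILE in conditions:
            m.dynamic_excursion[side.value] = commissure_excursion(
                face, side, Condition.SMILE
            )
            m.smile_excursion[side.value] = smile_excursion(face, side)

    if face.timepoint.value == "post" and Condition.SMILE in conditions:
        m.reanimation_class = classify_reanimation(
            m.smile_excursion[FunctionalSide.PARALYTIC.value].overall
        )
    return m


#: Evaluation-index names for pre/post differences, with their improvement
#: direction: 'pre_minus_post' for asymmetry-type indices (a decrease is an
#: improvement) and 'post_minus_pre' for excursion-type indices.
DIFFERENCE_INDEX_DIRECTIONS = {
    "d_static_fai": "pre_minus_post",
    "d_dynamic_fai": "pre_minus_post",
    "d_static_overall_excursion_paralytic": "post_minus_pre",
    "d_dynamic_overall_excursion_paralytic": "post_minus_pre",
    "d_static_philtrum_dev": "pre_minus_post",
    "d_dynamic_philtrum_dev": "pre_minus_post",
    "restoration_dynamic_slope_angle": "pre_minus_post",
}


@dataclass
class MetricDifferences:
    """Signed pre→post changes of the evaluation indices, improvement positive.

    An index whose operands are unavailable at either timepoint is listed
    in ``missing`` rather than silently reported as zero.
    """

    patient_id: str
    values: dict = field(default_factory=dict)
    missing: list = field(default_factory=list)


def _diff(direction: str, pre: Optional[float], post: Optional[float]) -> Optional[float]:
    if pre is None or post is None:
        return None
    return pre - post if direction == "pre_minus_post" else post - pre


def metric_differences(pre: SymmetryMetrics, post: SymmetryMetrics) -> MetricDifferences:
    if pre.patient_id != post.patient_id:
        raise ValueError(
            f"timepoints belong to different patients: {pre.patient_id} vs {post.patient_id}"
        )
    par = FunctionalSide.PARALYTIC.value
    rest, smile = Condition.REST.value, Condition.SMILE.value

    def overall(store):
        fgo = store.get(par)
        return fgo[2] if fgo is not None else None

    def absval(x):
        return abs(x) if x is not None else None

    operands = {
        "d_static_fai": (pre.fai_rest, post.fai_rest),
        "d_dynamic_fai": (pre.fai_smile, post.fai_smile),
        "d_static_overall_excursion_paralytic": (
            overall(pre.static_excursion),
            overall(post.static_excursion),
        ),
        "d_dynamic_overall_excursion_paralytic": (
            overall(pre.dynamic_excursion),
            overall(post.dynamic_excursion),
        ),
        "d_static_philtrum_dev": (
            absval(pre.philtrum_dev.get(rest)),
            absval(post.philtrum_dev.get(rest)),
        ),
        "d_dynamic_philtrum_dev": (
            absval(pre.philtrum_dev.get(smile)),
            absval(post.philtrum_dev.get(smile)),
        ),
        "restoration_dynamic_slope_angle": (
            absval(pre.slope_angle.get(smile)),
            absval(post.slope_angle.get(smile)),
        ),
    }
    out = MetricDifferences(patient_id=pre.patient_id)
    for name, (a, b) in operands.items():
        d = _diff(DIFFERENCE_INDEX_DIRECTIONS[name], a, b)
        if d is None:
            out.missing.append(name)
        else:
            out.values[name] = d
    return out
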