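"""Shared fixtures: a hand-constructed calibrated face with known geometry.

The canonical test face uses a white-to-white extent of 57.88 px, i.e. a
scale of exactly 0.2 mm/px, iris centers at (±50, 0), the reference point
at (0, 80) (image y grows downward, so the mouth is below the eyes), and
symmetric commissures whose face-frame components are f = 25 mm, g = 5 mm.
"""

import math

import numpy as np
import pytest

from facesym.landmarks import (
    AnnotatedFace,
    Condition,
    LandmarkSet,
    PatientMeta,
    Point2D,
)

WTW_PX = 57.88  # -> 0.2 mm per pixel
MM_PER_PX = 0.2


def default_points() -> dict[str, tuple[float, float]]:
    h = WTW_PX / 2.0
    return {
        "iris_center_left": (-50.0, 0.0),
        "iris_center_right": (50.0, 0.0),
        "limbus_medial_left": (-50.0 + h, 0.0),
        "limbus_lateral_left": (-50.0 - h, 0.0),
        "limbus_medial_right": (50.0 - h, 0.0),
        "limbus_lateral_right": (50.0 + h, 0.0),
        "medial_canthus_left": (-20.0, 5.0),
        "medial_canthus_right": (20.0, 5.0),
        "oral_commissure_left": (-125.0, 55.0),
        "oral_commissure_right": (125.0, 55.0),
        "philtrum": (0.0, 60.0),
        "eyelid_upper_left": (-50.0, -20.0),
        "eyelid_lower_left": (-50.0, 20.0),
        "eyelid_upper_right": (50.0, -20.0),
        "eyelid_lower_right": (50.0, 20.0),
    }


DEFAULT_VERMILION = [(-200.0, 80.0), (200.0, 80.0)]


def make_set(condition=Condition.REST, overrides=None, vermilion=None, drop=()):
    points = default_points()
    points.update(overrides or {})
    for name in drop:
        points.pop(name, None)
    return LandmarkSet(
        condition=condition,
        points={k: Point2D(*v) for k, v in points.items()},
        lower_lip_vermilion=[Point2D(*v) for v in (vermilion or DEFAULT_VERMILION)],
    )


def make_meta(paralyzed_side="left", **kwargs) -> PatientMeta:
    base = dict(
        id="T01",
        age=40.0,
        gender="female",
        cause="tumor",
        paralysis_duration=16.5,
        paralyzed_side=paralyzed_side,
        preop_fngs_grade=5,
        followup=12.0,
    )
    base.update(kwargs)
    return PatientMeta(**base)


def make_face(
    overrides_by_condition=None,
    timepoint="pre",
    paralyzed_side="left",
    conditions=(Condition.REST,),
    vermilion=None,
):
    """Face with paralyzed side left, so the healthy side is anatomical
    right, at positive image x: face-frame u > 0 is the +x half-plane."""
    overrides_by_condition = overrides_by_condition or {}
    sets = [
        make_set(c, overrides_by_condition.get(c), vermilion=vermilion)
        for c in conditions
    ]
    return AnnotatedFace.from_sets(make_meta(paralyzed_side), timepoint, sets)


def transform_face(face: AnnotatedFace, angle_deg=0.0, scale=1.0, shift=(0.0, 0.0)):
    """Apply a similarity transform to every pixel coordinate of a face."""
    th = math.radians(angle_deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    t = np.asarray(shift, dtype=float)

    def tp(p: Point2D) -> Point2D:
        xy = t + scale * (R @ p.as_array())
        return Point2D(float(xy[0]), float(xy[1]))

    sets = []
    for cond, lset in face.sets.items():
        sets.append(
            LandmarkSet(
                condition=cond,
                points={k: tp(p) for k, p in lset.points.items()},
                lower_lip_vermilion=[tp(p) for p in lset.lower_lip_vermilion],
            )
        )
    return AnnotatedFace.from_sets(face.meta, face.timepoint, sets)


def mirror_labels(face: AnnotatedFace) -> AnnotatedFace:
    """Swap anatomical left/right landmark labels and the paralyzed side,
    leaving all coordinates untouched."""

    def swap(name: str) -> str:
        if name.endswith("_left"):
            return name[: -len("_left")] + "_right"
        if name.endswith("_right"):
            return name[: -len("_right")] + "_left"
        return name

    sets = []
    for cond, lset in face.sets.items():
        sets.append(
            LandmarkSet(
                condition=cond,
                points={swap(k): p for k, p in lset.points.items()},
                lower_lip_vermilion=list(lset.lower_lip_vermilion),
            )
        )
    meta = face.meta.model_copy(
        update={"paralyzed_side": face.meta.paralyzed_side.other}
    )
    return AnnotatedFace.from_sets(meta, face.timepoint, sets)


@pytest.fixture
def symmetric_face():
    return make_face()


@pytest.fixture(scope="session")
def preop_preset():
    from facesym.simulate import reference_preop

    return reference_preop()


@pytest.fixture(scope="session")
def postop_preset():
    from facesym.simulate import reference_postop

    return reference_postop()
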