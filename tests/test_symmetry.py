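"""Facial-symmetry indices: worked geometry examples and invariances."""

import math

import numpy as np
import pytest

from facesym.errors import MissingLandmarkError
from facesym.landmarks import Condition, FunctionalSide
from facesym.symmetry import (
    GOOD_REANIMATION_THRESHOLD_MM,
    adjusted_horizontal,
    bilateral_slope_angle,
    classify_reanimation,
    commissure_angle,
    commissure_components,
    commissure_excursion,
    facial_asymmetry_index,
    measure_face,
    metric_differences,
    palpebral_fissure_width,
    philtrum_deviation,
    smile_excursion,
)

from conftest import MM_PER_PX, make_face, mirror_labels, transform_face

H, P = FunctionalSide.HEALTHY, FunctionalSide.PARALYTIC


class TestFacialAsymmetryIndex:
    def test_symmetric_face_scores_zero(self, symmetric_face):
        assert facial_asymmetry_index(symmetric_face) == pytest.approx(0.0, abs=1e-12)

    def test_matches_planar_distance_arithmetic(self):
        # canthus→commissure distances chosen to be 60.2080 mm (healthy)
        # and 55.0363 mm (paralytic) at 0.2 mm/px
        face = make_face(
            overrides_by_condition={
                Condition.REST: {
                    "oral_commissure_right": (20.0 + 60.2080 / MM_PER_PX, 5.0),
                    "oral_commissure_left": (-20.0 - 55.0363 / MM_PER_PX, 5.0),
                }
            }
        )
        assert facial_asymmetry_index(face) == pytest.approx(5.1717, abs=1e-9)

    def test_missing_commissure_is_named(self):
        face = make_face(
            overrides_by_condition={Condition.REST: {}},
        )
        del face.sets[Condition.REST].points["oral_commissure_left"]
        with pytest.raises(MissingLandmarkError, match="oral_commissure_left"):
            facial_asymmetry_index(face)


class TestPalpebralFissure:
    def test_full_closure_measures_zero(self):
        face = make_face(
            overrides_by_condition={
                Condition.REST: {
                    "eyelid_upper_right": (50.0, 0.0),
                    "eyelid_lower_right": (50.0, 0.0),
                }
            }
        )
        assert palpebral_fissure_width(face, H) == 0.0

    def test_forty_pixels_at_fifth_of_mm(self, symmetric_face):
        assert palpebral_fissure_width(symmetric_face, H) == pytest.approx(8.0)
        assert palpebral_fissure_width(symmetric_face, P) == pytest.approx(8.0)


class TestPhiltrumDeviation:
    def test_on_central_line_is_zero(self, symmetric_face):
        assert philtrum_deviation(symmetric_face) == pytest.approx(0.0, abs=1e-12)

    def test_signed_toward_healthy_side(self):
        face = make_face(
            overrides_by_condition={Condition.REST: {"philtrum": (18.05, 60.0)}}
        )
        assert philtrum_deviation(face) == pytest.approx(3.61, abs=1e-9)

    def test_relabelled_paralysis_side_flips_sign(self):
        # keep labels, move the paralysis flag to the other side: the
        # philtrum now deviates away from the healthy side
        face = make_face(
            overrides_by_condition={Condition.REST: {"philtrum": (18.05, 60.0)}},
            paralyzed_side="right",
        )
        assert philtrum_deviation(face) == pytest.approx(-3.61, abs=1e-9)


class TestCommissureGeometry:
    def test_components_at_known_face_coordinates(self, symmetric_face):
        c = commissure_components(symmetric_face, H)
        assert (c.f, c.g) == pytest.approx((25.0, 5.0), abs=1e-9)

    def test_symmetric_face_has_equal_components(self, symmetric_face):
        ch = commissure_components(symmetric_face, H)
        cp = commissure_components(symmetric_face, P)
        assert ch.f == pytest.approx(cp.f, abs=1e-12)
        assert ch.g == pytest.approx(cp.g, abs=1e-12)

    def test_rotation_invariance(self, symmetric_face):
        rotated = transform_face(symmetric_face, angle_deg=15.0, shift=(11.0, 7.0))
        for side in (H, P):
            c0 = commissure_components(symmetric_face, side)
            c1 = commissure_components(rotated, side)
            assert (c1.f, c1.g) == pytest.approx((c0.f, c0.g), abs=1e-6)

    def test_angle_zero_on_horizontal(self):
        face = make_face(
            overrides_by_condition={Condition.REST: {"oral_commissure_right": (125.0, 80.0)}}
        )
        assert commissure_angle(face, H) == pytest.approx(0.0, abs=1e-9)

    def test_angle_matches_arctan(self, symmetric_face):
        expected = math.degrees(math.atan(5.0 / 25.0))
        assert commissure_angle(symmetric_face, H) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(11.3099, abs=1e-4)

    def test_drooped_commissure_has_negative_angle(self):
        face = make_face(
            overrides_by_condition={Condition.REST: {"oral_commissure_left": (-125.0, 105.0)}}
        )
        assert commissure_angle(face, P) < 0.0

    def test_commissure_on_central_line_saturates_with_warning(self):
        face = make_face(
            overrides_by_condition={Condition.REST: {"oral_commissure_right": (0.0, 55.0)}}
        )
        with pytest.warns(UserWarning, match="central line"):
            assert commissure_angle(face, H) == 90.0

    def test_slope_angle_zero_for_level_commissures(self, symmetric_face):
        assert bilateral_slope_angle(symmetric_face) == pytest.approx(0.0, abs=1e-9)

    def test_slope_angle_matches_arctan(self):
        # g=5, g'=-5, f=f'=25  ->  arctan(10/50)
        face = make_face(
            overrides_by_condition={Condition.REST: {"oral_commissure_left": (-125.0, 105.0)}}
        )
        assert bilateral_slope_angle(face) == pytest.approx(
            math.degrees(math.atan(10.0 / 50.0)), abs=1e-6
        )

    def test_slope_angle_magnitude_survives_mirroring(self):
        face = make_face(
            overrides_by_condition={Condition.REST: {"oral_commissure_left": (-125.0, 105.0)}}
        )
        assert abs(bilateral_slope_angle(mirror_labels(face))) == pytest.approx(
            abs(bilateral_slope_angle(face)), abs=1e-9
        )


class TestAdjustedHorizontal:
    def test_reduces_to_f_when_philtrum_centered(self, symmetric_face):
        for side in (H, P):
            assert adjusted_horizontal(symmetric_face, side) == pytest.approx(
                commissure_components(symmetric_face, side).f, abs=1e-9
            )

    def test_sign_convention(self):
        # philtrum +3 mm toward healthy: healthy 25-3=22, paralytic 25+3=28
        face = make_face(
            overrides_by_condition={Condition.REST: {"philtrum": (15.0, 60.0)}}
        )
        assert adjusted_horizontal(face, H) == pytest.approx(22.0, abs=1e-9)
        assert adjusted_horizontal(face, P) == pytest.approx(28.0, abs=1e-9)

    def test_symmetric_face_has_zero_side_difference(self, symmetric_face):
        assert adjusted_horizontal(symmetric_face, H) - adjusted_horizontal(
            symmetric_face, P
        ) == pytest.approx(0.0, abs=1e-12)


class TestSmileExcursion:
    def test_no_movement_gives_zero(self):
        face = make_face(conditions=(Condition.REST, Condition.SMILE))
        exc = smile_excursion(face, H)
        assert (exc.dh, exc.dv, exc.overall) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_rest_50_smile_55_05(self):
        face = make_face(
            conditions=(Condition.REST, Condition.SMILE),
            overrides_by_condition={
                Condition.REST: {"oral_commissure_right": (250.0, 80.0)},
                Condition.SMILE: {"oral_commissure_right": (275.25, 80.0)},
            },
        )
        assert smile_excursion(face, H).overall == pytest.approx(5.05, abs=1e-9)

    def test_equals_brute_force_distance_difference(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            rest = tuple(rng.uniform([50, 30], [250, 150]))
            smile = tuple(rng.uniform([50, 30], [250, 150]))
            face = make_face(
                conditions=(Condition.REST, Condition.SMILE),
                overrides_by_condition={
                    Condition.REST: {"oral_commissure_right": rest},
                    Condition.SMILE: {"oral_commissure_right": smile},
                },
            )
            origin = face.frame.origin
            brute = MM_PER_PX * (
                math.hypot(smile[0] - origin.x, smile[1] - origin.y)
                - math.hypot(rest[0] - origin.x, rest[1] - origin.y)
            )
            assert smile_excursion(face, H).overall == pytest.approx(brute, abs=1e-9)

    def test_missing_smile_condition_raises(self, symmetric_face):
        with pytest.raises(MissingLandmarkError, match="SMILE"):
            smile_excursion(symmetric_face, H)


class TestReanimationClassification:
    @pytest.mark.parametrize(
        "excursion,expected", [(2.9, "poor"), (3.0, "good"), (5.05, "good")]
    )
    def test_threshold_rule(self, excursion, expected):
        assert classify_reanimation(excursion) == expected

    def test_agrees_with_direct_threshold_on_random_excursions(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(-1.0, 12.0, 10_000)
        for v in values:
            assert classify_reanimation(v) == (
                "poor" if v < GOOD_REANIMATION_THRESHOLD_MM else "good"
            )


class TestMetricDifferences:
    def test_identical_timepoints_give_zero_differences(self):
        pre = measure_face(make_face(conditions=(Condition.REST, Condition.SMILE)))
        post = measure_face(
            make_face(conditions=(Condition.REST, Condition.SMILE), timepoint="post")
        )
        d = metric_differences(pre, post)
        assert not d.missing
        for name, value in d.values.items():
            assert value == pytest.approx(0.0, abs=1e-9), name

    def test_static_fai_difference(self):
        pre = measure_face(make_face(conditions=(Condition.REST, Condition.SMILE)))
        post = measure_face(
            make_face(conditions=(Condition.REST, Condition.SMILE), timepoint="post")
        )
        pre.fai_rest, post.fai_rest = 4.87, 1.46
        assert metric_differences(pre, post).values["d_static_fai"] == pytest.approx(3.41)

    def test_missing_smile_flags_dynamic_indices(self):
        pre = measure_face(make_face(conditions=(Condition.REST, Condition.SMILE)))
        post = measure_face(make_face(timepoint="post"))  # REST only
        d = metric_differences(pre, post)
        assert "d_dynamic_fai" in d.missing
        assert "d_dynamic_overall_excursion_paralytic" in d.missing
        assert "d_dynamic_fai" not in d.values


class TestGlobalInvariances:
    def test_similarity_transform_leaves_all_metrics(self):
        face = make_face(
            conditions=(Condition.REST, Condition.SMILE, Condition.EYE_CLOSURE),
            overrides_by_condition={
                Condition.REST: {"philtrum": (12.0, 61.0), "oral_commissure_left": (-120.0, 70.0)},
                Condition.SMILE: {"oral_commissure_right": (160.0, 40.0)},
            },
        )
        moved = transform_face(face, angle_deg=-23.0, scale=1.7, shift=(-300.0, 45.0))
        r0, r1 = measure_face(face).to_row(), measure_face(moved).to_row()
        assert set(r0) == set(r1)
        for key, v0 in r0.items():
            if isinstance(v0, float):
                assert r1[key] == pytest.approx(v0, abs=1e-6), key

    def test_mirroring_labels_and_flag_preserves_all_metrics(self):
        # relabelling both the landmarks and the paralyzed side leaves the
        # healthy/paralytic geometry - and hence every metric, signed ones
        # included (signs are defined relative to the paralysis) - intact
        face = make_face(
            overrides_by_condition={
                Condition.REST: {"philtrum": (18.05, 60.0), "oral_commissure_left": (-120.0, 70.0)}
            }
        )
        mirrored = mirror_labels(face)
        assert facial_asymmetry_index(mirrored) == pytest.approx(
            facial_asymmetry_index(face), abs=1e-9
        )
        assert philtrum_deviation(mirrored) == pytest.approx(
            philtrum_deviation(face), abs=1e-9
        )
        for side in (H, P):
            assert commissure_excursion(mirrored, side) == pytest.approx(
                commissure_excursion(face, side), abs=1e-9
            )

    def test_swapping_labels_alone_negates_signed_metrics(self):
        # with the paralysis flag fixed, relabelling moves the paralysis to
        # the other physical side: signed metrics negate, unsigned survive
        face = make_face(
            overrides_by_condition={Condition.REST: {"philtrum": (18.05, 60.0)}}
        )
        swapped = mirror_labels(face)
        swapped = swapped.__class__.from_sets(
            swapped.meta.model_copy(update={"paralyzed_side": face.meta.paralyzed_side}),
            swapped.timepoint,
            swapped.sets,
        )
        assert philtrum_deviation(swapped) == pytest.approx(
            -philtrum_deviation(face), abs=1e-9
        )
        assert facial_asymmetry_index(swapped) == pytest.approx(
            facial_asymmetry_index(face), abs=1e-9
        )
        assert abs(bilateral_slope_angle(swapped)) == pytest.approx(
            abs(bilateral_slope_angle(face)), abs=1e-9
        )
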