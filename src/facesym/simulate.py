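"""Synthetic faces and patient cohorts with known ground truth.

A symmetric millimetre-space face template is deformed by a per-patient
paralysis severity: the paralytic oral commissure droops, the philtrum
and commissure are dragged toward the healthy side by the resting tone
imbalance, the paralytic palpebral fissure widens, and voluntary smile
excursion on the paralytic side collapses to a residual.  Post-operative
faces attenuate the deformation by a recovery fraction.  Landmarks are
jittered with Gaussian annotation noise and emitted in pixel coordinates
under a random similarity transform (per patient-timepoint, since photos
from one session share scale), with limbus landmarks spanning the
standardized 11.576 mm white-to-white diameter so the measurement
pipeline must re-derive its own calibration.

The ``reference_preop`` / ``reference_postop`` presets are tuned by closed-form
mean matching: deformation parameters are solved (root-finding on exact
noise-free expectations over the severity distribution) so that the
*measured* cohort means of the graded indices equal the target summary
statistics.  No simulated draws enter the calibration.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import integrate, optimize, stats

from facesym.landmarks import (
    WHITE_TO_WHITE_MM,
    AnatomicalSide,
    AnnotatedFace,
    Condition,
    LandmarkSet,
    PatientMeta,
    Point2D,
    Timepoint,
)

# ------------------------------------------------------------ targets
# Cohort summary statistics the presets are matched to (mm / months).
PRE_STATIC_FAI_MM = 4.87
POST_STATIC_FAI_MM = 1.46
PRE_PHILTRUM_DEV_MM = 3.61
PRE_PHILTRUM_DEV_SMILE_MM = 7.74
PRE_CLOSURE_WIDTH_MM = 3.88
POST_CLOSURE_WIDTH_MM = 0.14
PRE_REST_WIDTH_PARALYTIC_MM = 9.07
HEALTHY_REST_WIDTH_MM = 8.23
PRE_SMILE_EXCURSION_MM = 0.19
POST_SMILE_EXCURSION_MM = 5.05
MEAN_TIME_TO_CONTRACTION_MONTHS = 2.32
#: Fractions of the study cohort with complete eye closure while biting.
PRE_P_FULL_CLOSURE = 3 / 20
POST_P_FULL_CLOSURE = 17 / 20


class FaceTemplate(BaseModel):
    """Symmetric healthy-face landmark geometry, millimetres.

    Coordinates are face-frame: origin at the lower-lip reference point,
    x toward the (future) healthy side, y superior.
    """

    iris_x: float = 31.0
    iris_y: float = 62.0
    canthus_x: float = 15.5
    canthus_y: float = 60.0
    commissure_x: float = 25.0
    commissure_y: float = 5.0
    philtrum_y: float = 16.0
    rest_aperture: float = HEALTHY_REST_WIDTH_MM
    vermilion_halfspan: float = 32.0
    vermilion_points: int = 9


class FaceGeneratorConfig(BaseModel):
    """Geometry and noise parameters for synthetic face generation.

    Deformation magnitudes are the values at severity 1; a face at
    severity s (post-operatively attenuated to ``s*(1-recovery_fraction)``)
    receives the proportional deformation.  Smile excursions are radial
    displacements of the commissure away from the reference point, which
    is exactly the quantity the smile-excursion index measures.
    """

    template: FaceTemplate = Field(default_factory=FaceTemplate)
    droop: float = 7.0  # mm vertical commissure drop at severity 1
    lateral_pull: float = 5.157  # mm philtrum/commissure shift toward healthy side
    smile_pull_extra: float = 5.9  # additional philtrum pull during smile
    fissure_widening: float = 1.2  # mm paralytic rest-aperture widening
    smile_gain_healthy: float = 7.5  # mm radial smile excursion, healthy side
    smile_gain_paralytic: float = 7.13  # mm at full smile-function recovery
    smile_residual_paralytic: float = PRE_SMILE_EXCURSION_MM  # mm residual when flaccid
    recovery_fraction: float = 0.0  # 0 = pre-operative state
    closure_p_full: float = PRE_P_FULL_CLOSURE  # P(complete eye closure)
    closure_gap_mean: float = 4.6  # mm mean residual gap when closure incomplete
    landmark_noise_sd: float = 0.4  # mm isotropic annotation jitter
    lid_gap_noise_sd: float = 0.05  # mm per-lid jitter about the true aperture
    wtw_mm: float = WHITE_TO_WHITE_MM
    severity_alpha: float = 7.0  # severity ~ Beta(alpha, beta)
    severity_beta: float = 3.0
    px_per_mm_range: tuple[float, float] = (3.5, 5.5)
    max_rotation_deg: float = 5.0

    def severity_mean(self) -> float:
        return self.severity_alpha / (self.severity_alpha + self.severity_beta)


# ------------------------------------------------------------ closed forms


def closed_form_metrics(cfg: FaceGeneratorConfig, severity: float, stage="pre") -> dict:
    """Noise-free values of the key indices for one face at a given severity."""
    t = cfg.template
    stage = Timepoint(stage)
    s = severity * (1.0 - cfg.recovery_fraction) if stage is Timepoint.POST else severity
    dx0 = t.commissure_x - t.canthus_x
    dy0 = t.canthus_y - t.commissure_y
    healthy_dist = math.hypot(dx0, dy0)
    paralytic_dist = math.hypot(dx0 - cfg.lateral_pull * s, dy0 + cfg.droop * s)
    f_h, g_h = t.commissure_x, t.commissure_y
    f_p = abs(-t.commissure_x + cfg.lateral_pull * s)
    g_p = t.commissure_y - cfg.droop * s
    r = cfg.recovery_fraction if stage is Timepoint.POST else 0.0
    smile_par = cfg.smile_residual_paralytic + (
        cfg.smile_gain_paralytic - cfg.smile_residual_paralytic
    ) * r
    return {
        "fai_rest": abs(paralytic_dist - healthy_dist),
        "philtrum_dev_rest": cfg.lateral_pull * s,
        "philtrum_dev_smile": (cfg.lateral_pull + cfg.smile_pull_extra) * s,
        "slope_angle_rest": math.degrees(math.atan2(g_h - g_p, f_h + f_p)),
        "palpebral_rest_paralytic": t.rest_aperture + cfg.fissure_widening * s,
        "palpebral_rest_healthy": t.rest_aperture,
        "smile_excursion_healthy": cfg.smile_gain_healthy,
        "smile_excursion_paralytic": smile_par,
    }


def _severity_expectation(cfg: FaceGeneratorConfig, fn) -> float:
    """E[fn(severity)] under the Beta severity law, by adaptive quadrature."""
    pdf = stats.beta(cfg.severity_alpha, cfg.severity_beta).pdf
    val, _ = integrate.quad(lambda s: fn(s) * pdf(s), 0.0, 1.0, limit=200)
    return val


def expected_static_fai(cfg: FaceGeneratorConfig, stage="pre") -> float:
    """Exact noise-free cohort mean of the static FAI under the config."""
    return _severity_expectation(
        cfg, lambda s: closed_form_metrics(cfg, s, stage)["fai_rest"]
    )


def _folded_mean(g: float, sigma: float) -> float:
    """E|g + N(0, sigma^2)|, the folded-normal mean."""
    if sigma == 0.0:
        return abs(g)
    z = g / sigma
    return g * (1.0 - 2.0 * stats.norm.cdf(-z)) + 2.0 * sigma * stats.norm.pdf(z)


def expected_closure_width(
    p_full: float, gap_mean: float, lid_gap_noise_sd: float, cap: float
) -> float:
    """Expected measured paralytic fissure width in forced closure.

    The residual gap is 0 with probability ``p_full``, otherwise
    exponential with mean ``gap_mean`` truncated at the resting aperture
    ``cap``; the measured width folds in the per-lid placement noise
    (two lids → noise SD ``sqrt(2)*lid_gap_noise_sd``).
    """
    sigma = math.sqrt(2.0) * lid_gap_noise_sd
    closed = _folded_mean(0.0, sigma)
    if p_full >= 1.0:
        return closed
    m = gap_mean

    def integrand(g):
        return _folded_mean(g, sigma) * math.exp(-g / m) / m

    open_part, _ = integrate.quad(integrand, 0.0, cap, limit=200)
    open_part += math.exp(-cap / m) * _folded_mean(cap, sigma)
    return p_full * closed + (1.0 - p_full) * open_part


# ------------------------------------------------------------ presets


def reference_preop(**overrides) -> FaceGeneratorConfig:
    """Pre-operative preset matched to the printed cohort summary means.

    lateral_pull, smile_pull_extra and fissure_widening follow directly
    from linear mean matching at the severity mean; droop and the closure
    gap mean are solved by root-finding on the exact expectations.
    """
    cfg = FaceGeneratorConfig()
    s_mean = cfg.severity_mean()
    cfg = cfg.model_copy(
        update=dict(
            lateral_pull=PRE_PHILTRUM_DEV_MM / s_mean,
            smile_pull_extra=(PRE_PHILTRUM_DEV_SMILE_MM - PRE_PHILTRUM_DEV_MM) / s_mean,
            fissure_widening=(PRE_REST_WIDTH_PARALYTIC_MM - HEALTHY_REST_WIDTH_MM)
            / s_mean,
            recovery_fraction=0.0,
            closure_p_full=PRE_P_FULL_CLOSURE,
            smile_residual_paralytic=PRE_SMILE_EXCURSION_MM,
        )
    )

    def fai_gap(droop):
        return expected_static_fai(cfg.model_copy(update={"droop": droop})) - PRE_STATIC_FAI_MM

    droop = optimize.brentq(fai_gap, 0.05, 40.0, xtol=1e-10)
    cap = cfg.template.rest_aperture + cfg.fissure_widening * s_mean

    def closure_gap(mean_gap):
        return (
            expected_closure_width(cfg.closure_p_full, mean_gap, cfg.lid_gap_noise_sd, cap)
            - PRE_CLOSURE_WIDTH_MM
        )

    gap_mean = optimize.brentq(closure_gap, 1e-3, 30.0, xtol=1e-10)
    cfg = cfg.model_copy(update=dict(droop=droop, closure_gap_mean=gap_mean))
    return cfg.model_copy(update=overrides) if overrides else cfg


def reference_postop(**overrides) -> FaceGeneratorConfig:
    """Post-operative preset: the pre-operative geometry with a recovery
    fraction solved so the expected post-op static FAI matches its target,
    and the forced-closure mixture re-matched to the post-op mean."""
    pre = reference_preop()

    def fai_gap(r):
        return (
            expected_static_fai(pre.model_copy(update={"recovery_fraction": r}), stage="post")
            - POST_STATIC_FAI_MM
        )

    recovery = optimize.brentq(fai_gap, 0.0, 1.0, xtol=1e-12)
    s_mean = pre.severity_mean()
    cap = pre.template.rest_aperture + pre.fissure_widening * s_mean * (1 - recovery)

    def closure_gap(mean_gap):
        return (
            expected_closure_width(POST_P_FULL_CLOSURE, mean_gap, pre.lid_gap_noise_sd, cap)
            - POST_CLOSURE_WIDTH_MM
        )

    gap_mean = optimize.brentq(closure_gap, 1e-4, 30.0, xtol=1e-12)
    # Full-recovery smile gain such that at the solved recovery fraction the
    # expected paralytic smile excursion matches its post-op target.
    smile_gain = (
        PRE_SMILE_EXCURSION_MM
        + (POST_SMILE_EXCURSION_MM - PRE_SMILE_EXCURSION_MM) / recovery
    )
    cfg = pre.model_copy(
        update=dict(
            recovery_fraction=recovery,
            closure_p_full=POST_P_FULL_CLOSURE,
            closure_gap_mean=gap_mean,
            smile_gain_paralytic=smile_gain,
        )
    )
    return cfg.model_copy(update=overrides) if overrides else cfg


# ------------------------------------------------------------ face generation

DEFAULT_CONDITIONS = (Condition.REST, Condition.EYE_CLOSURE, Condition.SMILE)


def _default_meta(patient_id: str = "SYN", paralyzed_side="left") -> PatientMeta:
    return PatientMeta(
        id=patient_id,
        age=40.5,
        gender="female",
        cause="tumor",
        paralysis_duration=16.5,
        paralyzed_side=AnatomicalSide(paralyzed_side),
        preop_fngs_grade=5,
    )


def generate_face(
    cfg: FaceGeneratorConfig,
    severity: float,
    stage: Timepoint | str = Timepoint.PRE,
    meta: Optional[PatientMeta] = None,
    conditions: Sequence[Condition] = DEFAULT_CONDITIONS,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    closure_gap: Optional[float] = None,
) -> AnnotatedFace:
    """Generate one synthetic annotated face.

    ``severity`` in [0, 1] scales the paralysis deformation; at stage
    'post' it is attenuated by the config's recovery fraction.  The
    residual eyelid gap in forced closure may be supplied (cohort
    generation draws it as part of the patient's latent state) or is
    drawn here.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if rng is None:
        rng = np.random.default_rng(seed)
    stage = Timepoint(stage)
    meta = meta if meta is not None else _default_meta()
    t = cfg.template
    s = severity * (1.0 - cfg.recovery_fraction) if stage is Timepoint.POST else severity
    r = cfg.recovery_fraction if stage is Timepoint.POST else 0.0

    healthy = meta.healthy_side  # template +x side
    sign = {healthy: +1.0, healthy.other: -1.0}

    if closure_gap is None:
        if rng.random() < cfg.closure_p_full:
            closure_gap = 0.0
        else:
            closure_gap = float(rng.exponential(cfg.closure_gap_mean))
    paralytic_rest_aperture = t.rest_aperture + cfg.fissure_widening * s
    closure_gap = min(closure_gap, paralytic_rest_aperture)

    smile_par = cfg.smile_residual_paralytic + (
        cfg.smile_gain_paralytic - cfg.smile_residual_paralytic
    ) * r

    # one similarity transform per patient-timepoint (shared photo scale)
    ppm = rng.uniform(*cfg.px_per_mm_range)
    theta = math.radians(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    shift = rng.uniform(200.0, 800.0, size=2)

    def to_pixels(x_mm: float, y_mm: float) -> Point2D:
        # face mm (y up) -> image pixels (y down), rotated and scaled
        xi, yi = x_mm, -y_mm
        return Point2D(
            float(shift[0] + ppm * (cos_t * xi - sin_t * yi)),
            float(shift[1] + ppm * (sin_t * xi + cos_t * yi)),
        )

    noise = cfg.landmark_noise_sd

    def jitter(x, y):
        return x + rng.normal(0.0, noise), y + rng.normal(0.0, noise)

    sets = []
    for cond in conditions:
        cond = Condition(cond)
        points: dict[str, Point2D] = {}
        iris_mm: dict[AnatomicalSide, tuple[float, float]] = {}
        for side in (AnatomicalSide.LEFT, AnatomicalSide.RIGHT):
            sg = sign[side]
            ix, iy = jitter(sg * t.iris_x, t.iris_y)
            iris_mm[side] = (ix, iy)
            points[f"iris_center_{side.value}"] = to_pixels(ix, iy)
            # horizontal corneal extremes span the white-to-white diameter
            for label, off in (("medial", -sg * cfg.wtw_mm / 2), ("lateral", sg * cfg.wtw_mm / 2)):
                lx, ly = jitter(sg * t.iris_x + off, t.iris_y)
                points[f"limbus_{label}_{side.value}"] = to_pixels(lx, ly)
            cx, cy = jitter(sg * t.canthus_x, t.canthus_y)
            points[f"medial_canthus_{side.value}"] = to_pixels(cx, cy)

        # eyelids: on the vertical through the (annotated) iris center; the
        # lid pair shares its vertical-center jitter — the annotator marks
        # the aperture, not two independent points — with a small per-lid
        # residual so a closed lid measures near zero.
        for side in (AnatomicalSide.LEFT, AnatomicalSide.RIGHT):
            par = side == meta.paralyzed_side
            if cond is Condition.EYE_CLOSURE:
                aperture = closure_gap if par else 0.0
            else:
                aperture = paralytic_rest_aperture if par else t.rest_aperture
            ix, _ = iris_mm[side]
            center_y = t.iris_y + rng.normal(0.0, noise)
            half = aperture / 2.0
            eps_u = rng.normal(0.0, cfg.lid_gap_noise_sd)
            eps_l = rng.normal(0.0, cfg.lid_gap_noise_sd)
            points[f"eyelid_upper_{side.value}"] = to_pixels(ix, center_y + half + eps_u)
            points[f"eyelid_lower_{side.value}"] = to_pixels(ix, center_y - half - eps_l)

        # mouth region
        philtrum_x = cfg.lateral_pull * s
        if cond is Condition.SMILE:
            philtrum_x += cfg.smile_pull_extra * s
        px, py = jitter(philtrum_x, t.philtrum_y)
        points["philtrum"] = to_pixels(px, py)

        for side in (AnatomicalSide.LEFT, AnatomicalSide.RIGHT):
            sg = sign[side]
            par = side == meta.paralyzed_side
            cx = sg * t.commissure_x
            cy = t.commissure_y
            if par:
                cx += cfg.lateral_pull * s  # dragged toward healthy (+x) side
                cy -= cfg.droop * s
            if cond is Condition.SMILE:
                gain = smile_par if par else cfg.smile_gain_healthy
                radial = math.hypot(cx, cy)
                if radial > 0:
                    cx += gain * cx / radial
                    cy += gain * cy / radial
            cx, cy = jitter(cx, cy)
            points[f"oral_commissure_{side.value}"] = to_pixels(cx, cy)

        xs = np.linspace(-t.vermilion_halfspan, t.vermilion_halfspan, t.vermilion_points)
        vermilion = [to_pixels(*jitter(x, 0.0)) for x in xs]
        sets.append(
            LandmarkSet(condition=cond, points=points, lower_lip_vermilion=vermilion)
        )

    return AnnotatedFace.from_sets(meta, stage, sets)


# ------------------------------------------------------------ cohorts

PREDICTOR_NAMES = ("age", "female", "duration", "cause_trauma", "preop_fngs_grade")


class CohortGeneratorConfig(BaseModel):
    """Cohort-level covariate, outcome and time-to-event parameters.

    True model coefficients act on nominally standardized predictors
    (``(x - center) / scale`` with the centers/scales below; binary
    indicators enter raw), so their magnitudes are comparable across
    predictors.
    """

    n: int = Field(default=100, ge=1)
    seed: int = 0
    age_mean: float = 40.5
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 70.0)
    p_female: float = 0.5
    cause_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "tumor": 0.50,
            "bell_palsy": 0.25,
            "trauma": 0.20,
            "infection": 0.05,
        }
    )
    duration_log_mean: float = math.log(16.5)
    duration_log_sd: float = 0.9
    duration_range: tuple[float, float] = (2.0, 192.0)
    p_paralyzed_left: float = 0.5
    severity_alpha: float = 7.0  # per-patient severity ~ Beta(alpha, beta)
    severity_beta: float = 3.0
    predictor_centers: dict[str, float] = Field(
        default_factory=lambda: {"age": 40.5, "duration": 25.0, "preop_fngs_grade": 5.0}
    )
    predictor_scales: dict[str, float] = Field(
        default_factory=lambda: {"age": 12.0, "duration": 30.0, "preop_fngs_grade": 1.0}
    )
    effect_intercept: float = 1.0
    effect_coefs: dict[str, float] = Field(
        default_factory=lambda: {
            "age": -0.5,
            "female": 0.0,
            "duration": -0.5,
            "cause_trauma": 0.5,
            "preop_fngs_grade": 0.7,
        }
    )
    cox_coefs: dict[str, float] = Field(
        default_factory=lambda: {
            "age": -0.3,
            "female": 0.0,
            "duration": -0.4,
            "cause_trauma": 0.5,
            "preop_fngs_grade": 0.0,
        }
    )
    baseline_time_mean: float = MEAN_TIME_TO_CONTRACTION_MONTHS
    followup_range: tuple[float, float] = (6.6, 24.7)

    def model_post_init(self, _ctx) -> None:
        total = sum(self.cause_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"cause probabilities must sum to 1, got {total}")


@dataclass
class CohortTruth:
    """Everything needed to recompute expected cohort behaviour exactly."""

    cohort_config: dict
    face_config_pre: dict
    face_config_post: dict
    patients: pd.DataFrame  # per-patient latent state

    def to_json(self, path: str | Path) -> None:
        doc = {
            "cohort_config": self.cohort_config,
            "face_config_pre": self.face_config_pre,
            "face_config_post": self.face_config_post,
            "patients": self.patients.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, default=float) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            cohort_config=doc["cohort_config"],
            face_config_pre=doc["face_config_pre"],
            face_config_post=doc["face_config_post"],
            patients=pd.DataFrame(doc["patients"]),
        )


@dataclass
class Cohort:
    metas: list[PatientMeta]
    faces_pre: list[AnnotatedFace]
    faces_post: list[AnnotatedFace]
    fngs_items: pd.DataFrame
    sunnybrook_items: pd.DataFrame
    face_items: pd.DataFrame
    truth: CohortTruth


def _standardize(cfg: CohortGeneratorConfig, name: str, value: float) -> float:
    if name in cfg.predictor_centers:
        return (value - cfg.predictor_centers[name]) / cfg.predictor_scales[name]
    return value  # binary indicators enter raw


def _linear_predictor(cfg: CohortGeneratorConfig, coefs, intercept, predictors) -> float:
    lp = intercept
    for name in PREDICTOR_NAMES:
        lp += coefs.get(name, 0.0) * _standardize(cfg, name, predictors[name])
    return lp


def _grade_from_severity(severity: float) -> int:
    """Monotone staircase: severity → pre-operative FNGS grade 2–6."""
    for threshold, grade in ((0.15, 2), (0.35, 3), (0.55, 4), (0.75, 5)):
        if severity < threshold:
            return grade
    return 6


def _staircase(level: float, lo: int, hi: int) -> int:
    return int(min(hi, max(lo, round(level))))


def _fngs_items(severity: float, rng) -> dict:
    """Monotone map from severity to FNGS2.0 region scores (with ±1 jitter)."""
    base = 1.0 + 5.0 * severity
    offsets = {"brow": 1.0, "eye": -1.0, "nasolabial_fold": 0.3, "oral_commissure": 0.3}
    items = {
        k: _staircase(base + off + rng.normal(0, 0.4), 1, 6) for k, off in offsets.items()
    }
    items["synkinesis"] = _staircase(rng.normal(0.3, 0.5), 0, 3)
    return items


def _sunnybrook_items(severity: float, rng) -> dict:
    vol_offsets = {
        "brow_lift": -1.5,
        "gentle_eye_closure": 0.5,
        "open_mouth_smile": -0.3,
        "snarl": -0.3,
        "lip_pucker": -0.3,
    }
    items = {
        "resting_eye": _staircase(1.4 * severity + rng.normal(0, 0.25), 0, 1),
        "resting_cheek_nlf": _staircase(2.6 * severity + rng.normal(0, 0.3), 0, 2),
        "resting_mouth": _staircase(1.5 * severity + rng.normal(0, 0.25), 0, 1),
    }
    for k, off in vol_offsets.items():
        items[f"voluntary_{k}"] = _staircase(5.0 - 4.3 * severity + off + rng.normal(0, 0.4), 1, 5)
    for k in vol_offsets:
        items[f"synkinesis_{k}"] = _staircase(rng.normal(0.2, 0.4), 0, 3)
    return items


def _face_items(severity: float, rng) -> dict:
    """FaCE responses: items 1–3 higher=better, reverse-keyed items higher=worse."""
    items = {}
    for i in range(1, 16):
        if i <= 3:
            level = 5.0 - 4.3 * severity
        else:
            level = 1.0 + 4.0 * severity
        items[f"item_{i}"] = _staircase(level + rng.normal(0, 0.5), 1, 5)
    return items


def generate_cohort(
    cfg: CohortGeneratorConfig,
    face_cfg_pre: Optional[FaceGeneratorConfig] = None,
    face_cfg_post: Optional[FaceGeneratorConfig] = None,
    with_faces: bool = True,
) -> Cohort:
    """Generate a full synthetic cohort: faces, metadata, instrument items,
    dichotomous outcomes, event times, and the ground truth behind them.

    ``with_faces=False`` skips landmark synthesis (covariate/outcome-only
    studies); the random stream then differs from the with-faces cohort.
    """
    face_cfg_pre = face_cfg_pre if face_cfg_pre is not None else reference_preop()
    face_cfg_post = face_cfg_post if face_cfg_post is not None else reference_postop()
    rng = np.random.default_rng(cfg.seed)

    metas, faces_pre, faces_post = [], [], []
    fngs_rows, sb_rows, face_rows, truth_rows = [], [], [], []
    causes = sorted(cfg.cause_probs)
    cause_p = np.array([cfg.cause_probs[c] for c in causes])

    for i in range(cfg.n):
        pid = f"SYN{i:04d}"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), *cfg.age_range))
        female = bool(rng.random() < cfg.p_female)
        cause = str(rng.choice(causes, p=cause_p))
        duration = float(
            np.clip(rng.lognormal(cfg.duration_log_mean, cfg.duration_log_sd), *cfg.duration_range)
        )
        side = AnatomicalSide.LEFT if rng.random() < cfg.p_paralyzed_left else AnatomicalSide.RIGHT
        severity = float(rng.beta(cfg.severity_alpha, cfg.severity_beta))
        grade = _grade_from_severity(severity)

        predictors = {
            "age": age,
            "female": float(female),
            "duration": duration,
            "cause_trauma": float(cause == "trauma"),
            "preop_fngs_grade": float(grade),
        }
        lp_effect = _linear_predictor(cfg, cfg.effect_coefs, cfg.effect_intercept, predictors)
        p_good = 1.0 / (1.0 + math.exp(-lp_effect))
        y_good = bool(rng.random() < p_good)
        lp_cox = _linear_predictor(cfg, cfg.cox_coefs, 0.0, predictors)
        event_time = float(rng.exponential(cfg.baseline_time_mean) * math.exp(-lp_cox))
        followup = float(rng.uniform(*cfg.followup_range))
        event = event_time <= followup
        observed_time = min(event_time, followup)

        meta = PatientMeta(
            id=pid,
            age=age,
            gender="female" if female else "male",
            cause=cause,
            paralysis_duration=duration,
            paralyzed_side=side,
            preop_fngs_grade=grade,
            time_to_first_contraction=observed_time,
            followup=followup,
        )
        metas.append(meta)

        gap_pre = 0.0 if rng.random() < face_cfg_pre.closure_p_full else float(
            rng.exponential(face_cfg_pre.closure_gap_mean)
        )
        gap_post = 0.0 if rng.random() < face_cfg_post.closure_p_full else float(
            rng.exponential(face_cfg_post.closure_gap_mean)
        )
        if with_faces:
            faces_pre.append(
                generate_face(face_cfg_pre, severity, "pre", meta, rng=rng, closure_gap=gap_pre)
            )
            faces_post.append(
                generate_face(face_cfg_post, severity, "post", meta, rng=rng, closure_gap=gap_post)
            )

        post_severity = severity * (1.0 - face_cfg_post.recovery_fraction)
        for timepoint, sev in (("pre", severity), ("post", post_severity)):
            fngs_rows.append({"patient_id": pid, "timepoint": timepoint, **_fngs_items(sev, rng)})
            sb_rows.append({"patient_id": pid, "timepoint": timepoint, **_sunnybrook_items(sev, rng)})
            face_rows.append({"patient_id": pid, "timepoint": timepoint, **_face_items(sev, rng)})

        truth_rows.append(
            {
                "patient_id": pid,
                "severity": severity,
                "closure_gap_pre": gap_pre,
                "closure_gap_post": gap_post,
                "lp_effect": lp_effect,
                "p_good": p_good,
                "y_good": y_good,
                "lp_cox": lp_cox,
                "event_time": event_time,
                "followup": followup,
                "event": event,
                **predictors,
            }
        )

    truth = CohortTruth(
        cohort_config=cfg.model_dump(),
        face_config_pre=face_cfg_pre.model_dump(),
        face_config_post=face_cfg_post.model_dump(),
        patients=pd.DataFrame(truth_rows),
    )
    return Cohort(
        metas=metas,
        faces_pre=faces_pre,
        faces_post=faces_post,
        fngs_items=pd.DataFrame(fngs_rows),
        sunnybrook_items=pd.DataFrame(sb_rows),
        face_items=pd.DataFrame(face_rows),
        truth=truth,
    )


def ground_truth(
    cfg: CohortGeneratorConfig,
    face_cfg_pre: Optional[FaceGeneratorConfig] = None,
    face_cfg_post: Optional[FaceGeneratorConfig] = None,
) -> CohortTruth:
    """The exact generator parameters and per-patient latent state for a
    configuration (regenerated deterministically from its seed)."""
    return generate_cohort(cfg, face_cfg_pre, face_cfg_post).truth


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort in the formats the pipeline consumes: one landmark
    JSON per patient-timepoint, a metadata CSV, instrument item CSVs and
    the ground-truth JSON."""
    from facesym.io import write_landmarks_json, write_meta_csv

    outdir = Path(outdir)
    (outdir / "landmarks").mkdir(parents=True, exist_ok=True)
    for face in cohort.faces_pre + cohort.faces_post:
        path = outdir / "landmarks" / f"{face.meta.id}_{face.timepoint.value}.json"
        write_landmarks_json(face, path)
    write_meta_csv(cohort.metas, outdir / "meta.csv")
    cohort.fngs_items.to_csv(outdir / "fngs_items.csv", index=False)
    cohort.sunnybrook_items.to_csv(outdir / "sunnybrook_items.csv", index=False)
    cohort.face_items.to_csv(outdir / "face_items.csv", index=False)
    cohort.truth.to_json(outdir / "truth.json")
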