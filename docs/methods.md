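# Methods

## Coordinate model and calibration

Landmark files carry raw photograph coordinates (pixels, x rightward,
y downward). Every metric is computed in a face-centric orthonormal
frame: the x-axis runs along the inter-iris direction *toward the
healthy side*, the y-axis points superiorly, and the origin is the
reference point — the intersection of the facial central line (the
perpendicular bisector of the inter-iris segment) with the lower-lip
vermilion polyline. When the polyline crosses the central line more
than once the intersection nearest the inter-commissure midpoint is
used. Because the central line passes through both the inter-iris
midpoint and the origin, the superior axis is obtained by
Gram–Schmidt-orthogonalizing (midpoint − origin) against the x-axis;
the two constructions agree up to rounding.

Pixels convert to millimetres through the horizontal corneal
white-to-white diameter, standardized at 11.576 mm. The healthy eye
anchors the calibration by default: paralysis can distort the lid
aperture but not the limbus, yet the healthy side remains the
conservative choice; a both-eye mean is available
(`source_eye="mean"`), in which case the stored pixel extent is the
mean of the two eyes so the identity `mm_per_pixel × wtw_pixels =
11.576` always holds exactly. One calibration is shared by all of a
patient-timepoint's task conditions, since photographs from one session
share scale.

Sign conventions. The philtrum deviation and the vertical commissure
component g are signed with "toward the healthy side" / "superior"
positive. Signs are therefore defined *relative to the paralysis*, not
to anatomical left/right: relabelling the landmarks together with the
paralyzed-side flag leaves every metric (signed ones included)
unchanged, while relabelling the landmarks alone — which moves the
paralysis to the other physical side — negates the signed metrics.
All metrics are invariant to similarity transforms (rotation,
translation, uniform scaling) of the pixel coordinates to well below
1e−6 mm; geometric equality in tests uses that tolerance.

The angle of a commissure above the horizontal is arctan(g/f); the
caption symbol for the denominator is read as the horizontal component
f, the only horizontal distance defined alongside g. A commissure on
the central line (f = 0) returns ±90° with a warning rather than an
error. "Excursion" is deliberately split into three operations —
static (component distances at rest), dynamic (the same during smile),
and smile excursion (the rest→smile change in reference-point
distance) — because clinical usage overloads the term.

Pre→post evaluation indices are oriented so that improvement is
positive: asymmetry-type indices (FAI, philtrum deviation, slope angle)
as pre − post, excursion-type indices as post − pre. An index whose
operand is missing at either timepoint is reported as missing, never
as zero.

## Instrument scorers

FNGS2.0: the final grade maps from the four-region movement total
(4 → I; 5–9 → II; 10–14 → III; 15–19 → IV; 20–23 → V; 24 → VI). Grading
from the synkinesis-inclusive total is selectable by flag; the movement
mapping is the default because a regional profile of (6, 4, 5, 5) must
coexist with grade V. Sunnybrook: resting raw sum × 5 (0–20),
voluntary raw sum × 4 (20–100), synkinesis raw sum (0–15), composite =
voluntary − resting − synkinesis. FaCE: 15 items each 1–5;
reverse-keyed items are recoded as 6 − raw; each domain and the total
rescale linearly to 0–100 as (sum − n)/(4n) × 100. The item→domain map
and reverse-key list follow the original instrument and ship as an
editable module-level config so a translated variant with a different
structure can be substituted. Scorers are exact integer/rational
arithmetic; half-integer medians arise only from cohort aggregation.

## Prognostic models

Continuous predictors are z-scored and then power-transformed. A
Box-Cox step directly after z-scoring is ill-posed (z-scores are not
positive), so the transform is *shifted*: each column is offset by
1 − min(z) before Box-Cox with maximum-likelihood λ, and the transform
image of the training mean is subtracted so that a patient at the
training mean maps to exactly zero (the model intercept then reads as
the log-odds at the covariate mean). Binary indicators pass through
untouched. The stored spec (mean, SD, offset, λ, centering constant)
is reused — with clipping into the positive domain, under warning — on
new patients; the transform is exactly invertible on the training
domain.

Effect models are elastic-net-penalized logistic regressions
(scikit-learn saga solver), mixing parameter α = 0.5 by default, the
penalty chosen by 5-fold cross-validated deviance on a logarithmic grid
with a fixed fold seed; output is bit-reproducible given the seed. At a
vanishing penalty the fit matches the unpenalized maximum-likelihood
oracle to < 1e−3. Per evaluation index the predictor importance is
100·|β|/max|β| (all-zero vectors map to all zeros), which is scale-free
and permutation-equivariant. Continuous evaluation indices are
dichotomized at their median by default; the 3.0 mm good-reanimation
minimum is used for the post-operative smile-excursion outcome. A
dichotomized outcome that turns out constant (e.g. a threshold every
patient clears) skips its index with a warning. Below n = 30 the
package warns that cross-validated penalty selection is unstable — at
a clinical series of ~20 patients the refitted coefficients carry no
claim of validity, and the synthetic-cohort surface exists precisely so
the machinery can be validated at adequate n.

Time to the first biting-evoked facial contraction is modelled with Cox
proportional hazards (lifelines; Efron tie convention), 95% Wald
intervals, with explicit errors for all-censored input and
rank-deficient designs. Consistency is verified as monotone shrinkage
of the RMS log-hazard-ratio error over n ∈ {100, 400, 1600} (40
replicates per n); interval calibration as ≥93% coverage of a null
hazard ratio over 200 replicates.

## Synthetic cohort generator

A symmetric millimetre-space template (inter-iris 62 mm, resting
palpebral aperture 8.23 mm, commissures at (±25, 5) relative to the
reference point) is deformed by a per-patient paralysis severity
s ~ Beta(7, 3) (mean 0.7 — a cohort of mostly severe palsies):

* paralytic commissure droops by `droop`·s and is dragged toward the
  healthy side by `lateral_pull`·s;
* the philtrum shifts toward the healthy side by `lateral_pull`·s, plus
  `smile_pull_extra`·s during smile (healthy-side hypercontraction);
* the paralytic resting aperture widens by `fissure_widening`·s;
* in forced eye closure the healthy aperture is 0 and the paralytic
  aperture is a residual gap: 0 with probability `closure_p_full`,
  otherwise exponential with mean `closure_gap_mean`, truncated at the
  resting aperture;
* smile is a radial displacement of each commissure away from the
  reference point — exactly the quantity the smile-excursion index
  measures — of `smile_gain_healthy` on the healthy side and, on the
  paralytic side, a flaccid residual (0.19 mm) that recovers linearly
  in the post-operative recovery fraction.

Post-operative faces attenuate the static deformation to
s·(1 − `recovery_fraction`). Landmarks receive isotropic Gaussian
annotation jitter (0.4 mm SD — the repeatability of manual annotation
on clinical photographs) and are emitted in pixels under a random
similarity transform per patient-timepoint (3.5–5.5 px/mm, ±5°
rotation), with limbus landmarks spanning the standardized
white-to-white diameter so the measurement pipeline must re-derive its
own calibration. Eyelid landmarks are special-cased: the pair shares
its vertical-center jitter, with a small 0.05 mm per-lid residual,
because an annotator marks the lid aperture (a closed lid is a single
contact line), not two independent points; independent 0.4 mm noise on
both lids would impose a ~0.5 mm folded-noise floor on the measured
closure gap that real annotation does not show and that no parameter
choice could reconcile with a ~0.1 mm cohort mean.

Preset calibration is by **closed-form mean matching** only.
`lateral_pull`, `smile_pull_extra` and `fissure_widening` follow from
linear matching at the severity mean; `droop` solves
E[FAI(s)] = 4.87 mm by Brent root-finding on the exact noise-free
expectation under the Beta severity law (adaptive quadrature);
`closure_gap_mean` solves the expected measured closure width — the
folded-normal mean of gap-plus-lid-noise integrated over the truncated
exponential gap mixture — against the target (3.88 mm pre, 0.14 mm
post, with full-closure probabilities 3/20 and 17/20 as in the study
cohort); the post-operative `recovery_fraction` solves
E[FAI] = 1.46 mm, and the full-recovery smile gain places the expected
post-operative paralytic excursion at 5.05 mm. No simulated draw enters
any preset parameter. Landmark noise is unbiased to first order in
every matched metric; the largest second-order effect is the convexity
of the 1/white-to-white calibration ratio, ≈ +0.25% of the measured
mean (≈ 0.01 mm on the FAI), well inside Monte-Carlo error at the
n = 2000 used by the acceptance surface.

Severity also drives the cohort layer: the pre-operative FNGS grade via
a monotone staircase, instrument items via documented monotone maps
with small jitter, a Bernoulli good-outcome drawn from a logistic model
with configurable true coefficients on the five (nominally
standardized) predictors, and exponential times to first contraction
with baseline mean 2.32 months under a log-linear covariate effect,
censored at a uniform 6.6–24.7 month follow-up. The ground-truth object
records every parameter and per-patient latent value and regenerates
the identical cohort from its seed.

What the generator does *not* emulate: real annotation outliers and
occlusions, non-Gaussian landmark error, synkinetic co-movement
geometry, brow/snarl task deformations, correlation between
photographic severity and patient-reported items beyond the shared
severity scalar, and any joint distribution the source summary
statistics do not constrain. Passing tests therefore demonstrate that
the pipeline measures what the geometry contains and that the models
recover known structure at adequate n — not clinical validity on real
photographs.

## Numerical choices

Geometric equality: 1e−6 mm. Degenerate inputs raise typed errors
(coincident irises, zero white-to-white extent, vermilion not crossing
the central line, constant outcomes, all-censored times, rank-deficient
designs). Ties in the frame construction are broken toward the
inter-commissure midpoint. Paired comparisons: instrument totals by
Wilcoxon signed-rank (median/IQR summaries; exact null for small
tie-free samples, verified against full sign-enumeration), metric
values by two-tailed paired t (mean ± SD); no multiplicity correction
by default, Holm step-down available. Problem sizes in the test and
acceptance surfaces (2000-face cohorts; 10⁴–2·10⁴ random scorer inputs;
200 coverage replicates) were chosen so Monte-Carlo error is small
against the tolerances being checked while the full suite stays fast.
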