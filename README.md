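# facesym

Quantitative evaluation of facial reanimation after masseteric-to-facial
nerve transfer (MFNT): calibrated landmark photogrammetry of facial
symmetry, deterministic scorers for three facial-function instruments,
and prognostic models linking pre-operative clinical features to
surgical outcome — exercised end to end on synthetic patient cohorts
with known ground truth.

## Who this is for

Facial paralysis leaves one hemiface flaccid: the oral commissure
droops, the philtrum is dragged toward the healthy side by unopposed
muscle tone, the palpebral fissure widens, and voluntary smile excursion
collapses. Reanimation surgery aims to restore symmetry at rest and
during movement. Quantifying that recovery requires (i) millimetre-scale
measurements from clinical photographs, (ii) standardized clinician and
patient-reported grading, and (iii) models of which patients benefit.
This package implements all three stages as a reusable, tested pipeline
for methodologists and outcome researchers working from 2-D landmark
annotations (it does not detect landmarks from images).

## The measurements

All photograph coordinates are converted to millimetres using the
horizontal corneal **white-to-white diameter** (standardized at
11.576 mm) as an in-image ruler. The **central line** of the face is the
perpendicular bisector of the inter-iris segment; its intersection with
the lower-lip vermilion is the **reference point** from which commissure
geometry is measured. With f (g) the horizontal (vertical) distance of a
commissure from the central line (reference point), primes marking the
paralytic side:

* **FAI** (facial asymmetry index): |d<sub>paralytic</sub> − d<sub>healthy</sub>|
  of the medial-canthus → ipsilateral-commissure distances;
* **palpebral fissure width** on the vertical through the iris center;
* **philtrum deviation**: signed distance from the central line,
  positive toward the healthy side;
* **smile excursion**: rest→smile change of the reference-point →
  commissure distance;
* **commissure angle** arctan(g/f) and bilateral **slope angle**
  arctan((g−g′)/(f+f′));
* a post-operative paralytic smile excursion below **3.0 mm** classifies
  the reanimation as *poor* (the minimal excursion for a good result).

Instruments: **FNGS2.0** (four regions 1–6 + synkinesis 0–3, regional
total 4–24 mapped to grades I–VI), **Sunnybrook FGS** (composite =
4·voluntary − 5·resting − synkinesis, max 100), and the 15-item
**FaCE Scale** (six domains, each rescaled 0–100).

Prognosis: predictors (age, sex, paralysis duration, traumatic cause,
pre-operative FNGS grade) are z-scored and power-transformed, each
dichotomized evaluation index is fitted with an elastic-net-penalized
logistic model whose absolute coefficients are rescaled to 0–100
importances, and the time to the first biting-evoked facial contraction
is modelled with Cox proportional hazards.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
200-patient synthetic cohort (severities, covariates and outcomes drawn
from the generator's documented models):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_measure_symmetry.py
python analysis/03_score_instruments.py
python analysis/04_compare_pre_post.py
python analysis/05_fit_prognosis.py
```

`02_measure_symmetry.py` prints (cohort means, mm):

```
mean static FAI        pre  4.80 mm   post  1.53 mm
mean closure width     pre  4.01 mm   post  0.14 mm
mean smile excursion (paralytic) pre  0.16 mm   post  5.09 mm
good reanimation (>= 3.0 mm excursion): 100.0% of patients
```

i.e. the measurement pipeline recovers the geometry the generator was
matched to: static asymmetry drops from ~4.9 mm to ~1.5 mm, forced eye
closure becomes nearly complete, and paralytic smile excursion rises
from a flaccid trace to ~5 mm. `04_compare_pre_post.py` writes the
paired-test tables (Wilcoxon for ordinal scale totals, paired t for
metric values) to `results/comparisons.csv`, and `05_fit_prognosis.py`
prints the 0–100 importance table and the Cox summary; on this cohort
the Cox fit recovers the sign of every nonzero generator coefficient
(shorter paralysis duration, younger age and traumatic cause predict
earlier reinnervation).

A `facesym` CLI wraps the same stages (`simulate`, `measure`, `score`,
`compare`, `predict`, `report`) for use on external landmark/item files;
see `facesym --help` for the documented JSON/CSV schemas accepted.

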