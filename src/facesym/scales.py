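"""Deterministic scorers for the three facial-function instruments.

* **FNGS2.0** — clinician grading of four facial regions (brow, eye,
  nasolabial fold, oral commissure), each 1 (normal) … 6 (no movement),
  plus a synkinesis score 0–3.  The regional sum (4–24) maps to a final
  grade I–VI.
* **Sunnybrook FGS** — resting symmetry (3 items, weighted ×5), symmetry
  of five voluntary movements (1–5 each, weighted ×4) and synkinesis
  during those movements (0–3 each), combined into a composite
  ``voluntary − resting − synkinesis`` with a maximum of 100.
* **FaCE Scale** — 15 patient-reported items, each 1–5, grouped into six
  domains and rescaled linearly to 0–100 (higher = better) after
  reverse-keyed items are recoded.
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, Field

# ---------------------------------------------------------------- FNGS2.0

#: total_movement range → final grade (grade derived from movement only).
FNGS_GRADE_BINS = ((4, 4, 1), (5, 9, 2), (10, 14, 3), (15, 19, 4), (20, 23, 5), (24, 24, 6))


class FNGSInput(BaseModel):
    """Regional FNGS2.0 scores: 1 = normal movement … 6 = none."""

    brow: int = Field(ge=1, le=6)
    eye: int = Field(ge=1, le=6)
    nasolabial_fold: int = Field(ge=1, le=6)
    oral_commissure: int = Field(ge=1, le=6)
    synkinesis: int = Field(ge=0, le=3)


@dataclass(frozen=True)
class FNGSScore:
    total_movement: int
    total_with_synkinesis: int
    final_grade: int


def fngs_grade_from_total(total_movement: int) -> int:
    for lo, hi, grade in FNGS_GRADE_BINS:
        if lo <= total_movement <= hi:
            return grade
    raise ValueError(f"total movement {total_movement} outside 4–24")


def score_fngs(inp: FNGSInput, grade_includes_synkinesis: bool = False) -> FNGSScore:
    """Score an FNGS2.0 assessment.

    By default the final grade is mapped from the four-region movement
    total; set ``grade_includes_synkinesis`` to grade on the synkinesis-
    inclusive total instead (grades 5 and 6 then absorb the extra points).
    """
    if isinstance(inp, dict):
        inp = FNGSInput(**inp)
    total = inp.brow + inp.eye + inp.nasolabial_fold + inp.oral_commissure
    total_syn = total + inp.synkinesis
    basis = min(total_syn, 24) if grade_includes_synkinesis else total
    return FNGSScore(
        total_movement=total,
        total_with_synkinesis=total_syn,
        final_grade=fngs_grade_from_total(basis),
    )


# ---------------------------------------------------------------- Sunnybrook

SUNNYBROOK_MOVEMENTS = (
    "brow_lift",
    "gentle_eye_closure",
    "open_mouth_smile",
    "snarl",
    "lip_pucker",
)


class SunnybrookInput(BaseModel):
    """Raw Sunnybrook FGS item scores.

    Resting items score the *asymmetry* at rest (0 = normal); voluntary
    items score movement symmetry 1 (none) … 5 (complete); synkinesis
    items score 0 (none) … 3 (severe) per movement.
    """

    resting_eye: int = Field(ge=0, le=1)
    resting_cheek_nlf: int = Field(ge=0, le=2)
    resting_mouth: int = Field(ge=0, le=1)
    voluntary: dict[str, int]
    synkinesis: dict[str, int]

    def model_post_init(self, _ctx) -> None:
        for store, lo, hi, label in (
            (self.voluntary, 1, 5, "voluntary"),
            (self.synkinesis, 0, 3, "synkinesis"),
        ):
            if set(store) != set(SUNNYBROOK_MOVEMENTS):
                raise ValueError(
                    f"{label} items must be exactly {SUNNYBROOK_MOVEMENTS}, got {sorted(store)}"
                )
            for item, v in store.items():
                if not lo <= v <= hi:
                    raise ValueError(f"{label} item '{item}' = {v} outside {lo}–{hi}")


@dataclass(frozen=True)
class SunnybrookScore:
    resting_total: int  # 0–20, raw sum × 5
    voluntary_total: int  # 20–100, raw sum × 4
    synkinesis_total: int  # 0–15, raw sum
    composite: int  # voluntary − resting − synkinesis


def score_sunnybrook(inp: SunnybrookInput) -> SunnybrookScore:
    if isinstance(inp, dict):
        inp = SunnybrookInput(**inp)
    resting = 5 * (inp.resting_eye + inp.resting_cheek_nlf + inp.resting_mouth)
    voluntary = 4 * sum(inp.voluntary.values())
    synkinesis = sum(inp.synkinesis.values())
    return SunnybrookScore(
        resting_total=resting,
        voluntary_total=voluntary,
        synkinesis_total=synkinesis,
        composite=voluntary - resting - synkinesis,
    )


# ---------------------------------------------------------------- FaCE Scale

#: Item → domain map of the original 15-item instrument.  Shipped as an
#: editable module-level config so a translated variant with a different
#: structure can be swapped in.
FACE_DOMAINS: dict[str, tuple[int, ...]] = {
    "facial_movement": (1, 2, 3),
    "facial_comfort": (4, 5, 8),
    "oral_function": (6, 7),
    "eye_comfort": (9, 10),
    "lacrimal_control": (11,),
    "social_function": (12, 13, 14, 15),
}

#: Items whose raw response scale runs worst→best reversed (higher raw =
#: worse); they are recoded as ``6 − raw`` before rescaling.
FACE_REVERSE_ITEMS: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)


class FaCEInput(BaseModel):
    """Raw FaCE Scale responses: ``items[k]`` is the response (1–5) to item k."""

    items: dict[int, int]

    def model_post_init(self, _ctx) -> None:
        if set(self.items) != set(range(1, 16)):
            missing = sorted(set(range(1, 16)) - set(self.items))
            extra = sorted(set(self.items) - set(range(1, 16)))
            raise ValueError(f"FaCE items must be 1–15 (missing {missing}, extra {extra})")
        for k, v in self.items.items():
            if not 1 <= v <= 5:
                raise ValueError(f"FaCE item {k} = {v} outside 1–5")


@dataclass(frozen=True)
class FaCEScore:
    domains: dict[str, float]  # each 0–100
    total: float  # 0–100


def _rescale(recoded_sum: int, n_items: int) -> float:
    """Linear 0–100 rescale of a sum of n recoded 1–5 items."""
    return (recoded_sum - n_items) / (4 * n_items) * 100.0


def score_face_scale(
    inp: FaCEInput,
    domains: dict[str, tuple[int, ...]] = FACE_DOMAINS,
    reverse_items: tuple[int, ...] = FACE_REVERSE_ITEMS,
) -> FaCEScore:
    if isinstance(inp, dict):
        inp = FaCEInput(items=inp)
    recoded = {
        k: (6 - v if k in reverse_items else v) for k, v in inp.items.items()
    }
    domain_scores = {
        name: _rescale(sum(recoded[i] for i in items), len(items))
        for name, items in domains.items()
    }
    total = _rescale(sum(recoded.values()), 15)
    return FaCEScore(domains=domain_scores, total=total)
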