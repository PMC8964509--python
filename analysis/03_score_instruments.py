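#!/usr/bin/env python
"""Score the three facial-function instruments for the working cohort.

Reads the item tables written by 01_simulate_cohort.py, applies the
FNGS2.0, Sunnybrook FGS and FaCE scorers, and writes a combined long
table to results/scores.csv.  Prints the pre/post median totals.
"""

from pathlib import Path

import pandas as pd

from facesym.scales import (
    SUNNYBROOK_MOVEMENTS,
    score_face_scale,
    score_fngs,
    score_sunnybrook,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fngs = pd.read_csv(ROOT / "cohort" / "fngs_items.csv")
    sb = pd.read_csv(ROOT / "cohort" / "sunnybrook_items.csv")
    face = pd.read_csv(ROOT / "cohort" / "face_items.csv")

    rows = []
    for (_, f), (_, s), (_, q) in zip(fngs.iterrows(), sb.iterrows(), face.iterrows()):
        fs = score_fngs(
            {k: int(f[k]) for k in ("brow", "eye", "nasolabial_fold", "oral_commissure", "synkinesis")}
        )
        ss = score_sunnybrook(
            {
                "resting_eye": int(s["resting_eye"]),
                "resting_cheek_nlf": int(s["resting_cheek_nlf"]),
                "resting_mouth": int(s["resting_mouth"]),
                "voluntary": {m: int(s[f"voluntary_{m}"]) for m in SUNNYBROOK_MOVEMENTS},
                "synkinesis": {m: int(s[f"synkinesis_{m}"]) for m in SUNNYBROOK_MOVEMENTS},
            }
        )
        qs = score_face_scale({i: int(q[f"item_{i}"]) for i in range(1, 16)})
        rows.append(
            {
                "patient_id": f["patient_id"],
                "timepoint": f["timepoint"],
                "fngs_total_movement": fs.total_movement,
                "fngs_final_grade": fs.final_grade,
                "sb_resting_total": ss.resting_total,
                "sb_voluntary_total": ss.voluntary_total,
                "sb_synkinesis_total": ss.synkinesis_total,
                "sb_composite": ss.composite,
                "face_total": qs.total,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "scores.csv", index=False)
    print(f"scored {len(df)} assessments -> {ROOT / 'scores.csv'}")
    for col in ("fngs_final_grade", "sb_composite", "face_total"):
        med = df.groupby("timepoint")[col].median()
        print(f"median {col:18s} pre {med['pre']:6.1f}   post {med['post']:6.1f}")


if __name__ == "__main__":
    main()
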