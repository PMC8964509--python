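#!/usr/bin/env python
"""Paired pre/post comparisons of the working cohort.

Instrument totals are compared with the Wilcoxon matched-pairs
signed-rank test (median/IQR summaries), symmetry metrics with the
two-tailed paired t test (mean ± SD).  Writes results/comparisons.csv
and a Markdown rendering to results/report.md.
"""

from pathlib import Path

import pandas as pd

from facesym.reporting import build_report, report_to_markdown

ROOT = Path(__file__).resolve().parent.parent / "results"

METRIC_COLS = [
    "fai_rest",
    "fai_smile",
    "philtrum_dev_REST",
    "palpebral_paralytic_REST",
    "palpebral_paralytic_EYE_CLOSURE",
    "smile_excursion_overall_paralytic",
    "slope_angle_REST",
    "slope_angle_SMILE",
]
SCORE_COLS = [
    "fngs_total_movement",
    "fngs_final_grade",
    "sb_resting_total",
    "sb_voluntary_total",
    "sb_synkinesis_total",
    "sb_composite",
    "face_total",
]


def main() -> None:
    metrics = pd.read_csv(ROOT / "metrics.csv")
    scores = pd.read_csv(ROOT / "scores.csv")
    tables = build_report(metrics, scores, metric_cols=METRIC_COLS, score_cols=SCORE_COLS)
    combined = pd.concat(
        [df.assign(table=name) for name, df in tables.items()], ignore_index=True
    )
    combined.to_csv(ROOT / "comparisons.csv", index=False)
    (ROOT / "report.md").write_text(report_to_markdown(tables))
    print(f"wrote {len(combined)} comparisons -> {ROOT / 'comparisons.csv'}")
    for _, row in combined.iterrows():
        print(
            f"{row['variable']:34s} {row['method']:9s} pre {row['pre']:>16s} "
            f"post {row['post']:>16s} p={row['p_value']:.2e}"
        )


if __name__ == "__main__":
    main()
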