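"""Cohort-level pre/post comparisons and summary-report assembly.

Instrument scores (ordinal) are compared with the Wilcoxon matched-pairs
signed-rank test and summarized as median (IQR); millimetre/degree
metrics with the two-tailed paired t test and mean ± SD.  No
multiple-testing correction is applied by default; Holm adjustment is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from facesym.errors import ModelError


@dataclass(frozen=True)
class PairedComparison:
    variable: str
    method: str  # 'paired_t' | 'wilcoxon'
    statistic: float
    p_value: float
    pre_summary: str
    post_summary: str
    n: int


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q3 - q1:g})"


def paired_compare(
    pre, post, method: str = "paired_t", variable: str = ""
) -> PairedComparison:
    """Two-sided paired comparison of pre vs post values (aligned by patient)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    if len(pre) < 3:
        raise ModelError(f"'{variable}': need at least 3 pairs, got {len(pre)}")
    diffs = post - pre
    if method == "paired_t":
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise ModelError(f"'{variable}': zero-variance differences; paired t undefined")
        res = stats.ttest_rel(post, pre)
        pre_s, post_s = _mean_sd(pre), _mean_sd(post)
    elif method == "wilcoxon":
        if np.all(diffs == 0):
            raise ModelError(f"'{variable}': all pairs tied; signed-rank test undefined")
        res = stats.wilcoxon(post, pre, zero_method="wilcox", method="auto")
        pre_s, post_s = _median_iqr(pre), _median_iqr(post)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedComparison(
        variable=variable,
        method=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        pre_summary=pre_s,
        post_summary=post_s,
        n=len(pre),
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def comparisons_table(comparisons: list[PairedComparison], holm: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "variable": c.variable,
                "method": c.method,
                "n": c.n,
                "pre": c.pre_summary,
                "post": c.post_summary,
                "statistic": c.statistic,
                "p_value": c.p_value,
            }
            for c in comparisons
        ]
    )
    if holm and len(df):
        df["p_holm"] = holm_adjust(df["p_value"].tolist())
    return df


def _paired_frame(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Pivot a long patient/timepoint table to aligned pre/post columns."""
    wide = df.pivot(index="patient_id", columns="timepoint", values=value_cols)
    pre_ids = set(df.loc[df.timepoint == "pre", "patient_id"])
    post_ids = set(df.loc[df.timepoint == "post", "patient_id"])
    unmatched = sorted(pre_ids ^ post_ids)
    if unmatched:
        raise ModelError(f"patients present at only one timepoint: {unmatched}")
    return wide


def build_report(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    metric_cols: list[str] | None = None,
    score_cols: list[str] | None = None,
    holm: bool = False,
) -> dict[str, pd.DataFrame]:
    """Assemble pre/post comparison tables from long-format cohort tables.

    Both inputs need ``patient_id`` and ``timepoint`` ('pre'/'post')
    columns.  Scale scores are compared by Wilcoxon signed-rank and
    summarized as median (IQR); metrics by paired t and mean ± SD.
    Output ordering is deterministic (input column order).
    """
    if metrics.empty or scores.empty:
        raise ModelError("empty cohort: nothing to report")
    out = {}
    for name, df, method, cols in (
        ("instruments", scores, "wilcoxon", score_cols),
        ("metrics", metrics, "paired_t", metric_cols),
    ):
        cols = cols or [
            c
            for c in df.columns
            if c not in ("patient_id", "timepoint") and pd.api.types.is_numeric_dtype(df[c])
        ]
        wide = _paired_frame(df, cols)
        comps = []
        for col in cols:
            pair = wide[col].dropna()
            if pair.empty or "pre" not in pair or "post" not in pair:
                continue
            try:
                comps.append(
                    paired_compare(pair["pre"], pair["post"], method=method, variable=col)
                )
            except ModelError:
                continue  # untestable variable (all tied); leave it out of the table
        out[name] = comparisons_table(comps, holm=holm)
    return out


def report_to_markdown(tables: dict[str, pd.DataFrame]) -> str:
    lines = []
    for name, df in tables.items():
        lines.append(f"## {name}")
        lines.append(df.to_markdown(index=False))
        lines.append("")
    return "\n".join(lines)
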