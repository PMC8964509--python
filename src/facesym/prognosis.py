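"""Prognostic models for reanimation outcome.

Pipeline: predictors (age, female, duration of paralysis, traumatic
cause, pre-operative FNGS grade) are z-scored and power-transformed;
each dichotomized evaluation index is regressed on them with an
elastic-net-penalized logistic model whose absolute coefficients are
rescaled to a 0–100 importance; the time to the first biting-evoked
facial contraction is modelled with Cox proportional hazards.

Z-scored predictors are not positive, so the power step is a *shifted*
Box-Cox: each column is offset by ``1 - min`` before the transform and
the offset is stored for reuse on new patients.  λ is chosen by maximum
likelihood on the training column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from facesym.errors import ModelError

PREDICTOR_COLUMNS = ("age", "female", "duration", "cause_trauma", "preop_fngs_grade")

#: Below this sample size cross-validated penalty selection is unstable.
SMALL_SAMPLE_WARNING_N = 30


# ------------------------------------------------------------ preprocessing


@dataclass
class ColumnTransform:
    mean: float
    sd: float
    offset: float  # positivity shift applied after z-scoring
    lmbda: float  # Box-Cox exponent (maximum likelihood)
    center: float  # transform image of the training mean, subtracted so the
    # training mean maps to exactly 0 (the intercept then reads as the
    # log-odds at the covariate mean)


@dataclass
class PreprocessSpec:
    """Stored per-column transforms; binary indicators pass through."""

    columns: dict[str, ColumnTransform] = field(default_factory=dict)
    passthrough: list[str] = field(default_factory=list)


def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def preprocess(design: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessSpec]:
    """Z-score then shifted-Box-Cox each continuous column.

    Binary indicator columns are passed through untouched.  Raises on a
    constant column, naming it.
    """
    spec = PreprocessSpec()
    out = {}
    for col in design.columns:
        x = design[col].astype(float)
        if _is_binary(x):
            spec.passthrough.append(col)
            out[col] = x.to_numpy()
            continue
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ModelError(f"column '{col}' is constant; cannot standardize")
        mean = float(x.mean())
        z = (x.to_numpy() - mean) / sd
        offset = 1.0 - float(z.min())
        transformed, lmbda = stats.boxcox(z + offset)
        center = float(stats.boxcox(np.array([offset]), lmbda=float(lmbda))[0])
        spec.columns[col] = ColumnTransform(
            mean=mean, sd=sd, offset=offset, lmbda=float(lmbda), center=center
        )
        out[col] = transformed - center
    return pd.DataFrame(out, index=design.index), spec


def apply_preprocess(design: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    """Apply a stored spec to new patients (clipping into the positive
    domain of the transform, with a warning, when needed)."""
    out = {}
    for col in design.columns:
        x = design[col].astype(float).to_numpy()
        if col in spec.passthrough:
            out[col] = x
            continue
        if col not in spec.columns:
            raise ModelError(f"no stored transform for column '{col}'")
        t = spec.columns[col]
        shifted = (x - t.mean) / t.sd + t.offset
        if np.any(shifted <= 0):
            warnings.warn(
                f"column '{col}': values outside the training domain clipped "
                "to keep the power transform defined",
                stacklevel=2,
            )
            shifted = np.clip(shifted, 1e-8, None)
        out[col] = stats.boxcox(shifted, lmbda=t.lmbda) - t.center
    return pd.DataFrame(out, index=design.index)


def inverse_preprocess(transformed: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    out = {}
    for col in transformed.columns:
        x = transformed[col].astype(float).to_numpy()
        if col in spec.passthrough:
            out[col] = x
            continue
        t = spec.columns[col]
        out[col] = (special.inv_boxcox(x + t.center, t.lmbda) - t.offset) * t.sd + t.mean
    return pd.DataFrame(out, index=transformed.index)


# ------------------------------------------------------------ effect model


@dataclass
class EffectModel:
    coefficients: pd.Series  # per-predictor, on the transformed scale
    intercept: float
    C: float  # selected inverse penalty strength
    l1_ratio: float

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.coefficients.index].to_numpy() @ self.coefficients.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return special.expit(self.linear_predictor(X))


def dichotomize(values: pd.Series, rule: str | float = "median") -> pd.Series:
    """Binary outcome from a continuous evaluation index.

    ``rule='median'`` splits at the sample median (above = 1); a numeric
    rule is an absolute threshold (``>= rule`` = 1), e.g. the 3.0 mm
    good-reanimation minimum for post-operative smile excursion.
    """
    if rule == "median":
        threshold = float(values.median())
        return (values > threshold).astype(int)
    return (values >= float(rule)).astype(int)


def fit_effect_model(
    X: pd.DataFrame,
    y: Sequence[int],
    l1_ratio: float = 0.5,
    Cs: Optional[Sequence[float]] = None,
    folds: int = 5,
    seed: int = 0,
    C: Optional[float] = None,
) -> EffectModel:
    """Elastic-net-regularized logistic regression.

    The penalty is selected by ``folds``-fold cross-validated deviance on
    a logarithmic grid (deterministic given ``seed``); pass ``C`` to skip
    selection and fit at a fixed inverse penalty.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("outcome is constant; logistic model undefined")
    n = len(y)
    if n < folds:
        raise ModelError(f"n={n} is smaller than the number of CV folds ({folds})")
    if n < SMALL_SAMPLE_WARNING_N:
        warnings.warn(
            f"n={n} < {SMALL_SAMPLE_WARNING_N}: cross-validated penalty selection "
            "is unstable at this sample size",
            stacklevel=2,
        )
    if C is None:
        Cs = np.logspace(-3, 3, 21) if Cs is None else np.asarray(Cs, dtype=float)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        model = LogisticRegressionCV(
            Cs=Cs,
            cv=cv,
            scoring="neg_log_loss",
            solver="saga",
            max_iter=20000,
            tol=1e-8,
            l1_ratios=[l1_ratio],
            random_state=seed,
        )
        model.fit(X.to_numpy(), y)
        chosen_C = float(model.C_[0])
    else:
        model = LogisticRegression(
            C=C,
            l1_ratio=l1_ratio,
            solver="saga",
            max_iter=20000,
            tol=1e-8,
            random_state=seed,
        )
        model.fit(X.to_numpy(), y)
        chosen_C = float(C)
    return EffectModel(
        coefficients=pd.Series(model.coef_[0], index=list(X.columns)),
        intercept=float(model.intercept_[0]),
        C=chosen_C,
        l1_ratio=l1_ratio,
    )


def importance_scale(coefficients: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Scale absolute coefficients to a 0–100 importance.

    The largest-magnitude coefficient maps to 100; an all-zero vector
    maps to all zeros.  Scale-free: multiplying every coefficient by a
    positive constant leaves the importances unchanged.
    """
    values = np.abs(np.asarray(coefficients, dtype=float))
    top = values.max() if values.size else 0.0
    scaled = np.zeros_like(values) if top == 0.0 else 100.0 * values / top
    if isinstance(coefficients, pd.Series):
        return pd.Series(scaled, index=coefficients.index)
    return scaled


def fit_importance_table(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    dichotomize_rules: Optional[dict] = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, EffectModel]]:
    """Fit one effect model per evaluation index.

    Returns (coefficient table, 0–100 importance table, fitted models),
    both tables with one row per index and one column per predictor.
    An index whose dichotomized outcome is constant (e.g. a fixed
    clinical threshold that every patient clears) is skipped with a
    warning rather than aborting the table.
    """
    dichotomize_rules = dichotomize_rules or {}
    coef_rows, imp_rows, models = {}, {}, {}
    for index_name in outcomes.columns:
        col = outcomes[index_name].dropna()
        rule = dichotomize_rules.get(index_name, "median")
        y = dichotomize(col, rule) if col.nunique() > 2 else col.astype(int)
        if y.nunique() < 2:
            warnings.warn(
                f"evaluation index '{index_name}': dichotomized outcome is "
                "constant; index skipped",
                stacklevel=2,
            )
            continue
        model = fit_effect_model(X.loc[col.index], y, **fit_kwargs)
        models[index_name] = model
        coef_rows[index_name] = model.coefficients
        imp_rows[index_name] = importance_scale(model.coefficients)
    return (
        pd.DataFrame(coef_rows).T,
        pd.DataFrame(imp_rows).T,
        models,
    )


# ------------------------------------------------------------ Cox model


@dataclass
class CoxResult:
    """Per-predictor partial-likelihood estimates (Efron tie handling)."""

    summary: pd.DataFrame  # log_hr, hr, ci_lower, ci_upper, p
    concordance: float


def fit_time_to_contraction(
    X: pd.DataFrame, times: Sequence[float], events: Sequence[bool]
) -> CoxResult:
    """Cox proportional-hazards model of the time to first facial
    contraction, 95% Wald intervals, ties handled by the Efron convention."""
    from lifelines import CoxPHFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ModelError("negative event times")
    if not events.any():
        raise ModelError("all observations censored; Cox model undefined")
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm - Xm.mean(axis=0)) < Xm.shape[1]:
        raise ModelError("rank-deficient design (collinear or constant predictors)")
    df = X.copy()
    df["_time"] = times
    df["_event"] = events.astype(int)
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="_time", event_col="_event")
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "log_hr": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxResult(summary=summary, concordance=float(fitter.concordance_index_))


# ------------------------------------------------------------ prediction


def predict_prognosis(
    new_patients: pd.DataFrame,
    spec: PreprocessSpec,
    effect_models: dict[str, EffectModel],
    cox_coefficients: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Apply stored preprocessing and fitted models to new patients.

    Returns per-index predicted probabilities and classes, plus (when Cox
    coefficients are given) a relative risk score whose ranking predicts
    the order of expected time to first contraction (higher score =
    earlier contraction).
    """
    missing = [c for c in list(spec.columns) + spec.passthrough if c not in new_patients.columns]
    if missing:
        raise ModelError(f"missing predictor columns: {missing}")
    Xt = apply_preprocess(new_patients[list(spec.columns) + spec.passthrough], spec)
    out = pd.DataFrame(index=new_patients.index)
    for name, model in effect_models.items():
        proba = model.predict_proba(Xt)
        out[f"p_{name}"] = proba
        out[f"class_{name}"] = (proba >= 0.5).astype(int)
    if cox_coefficients is not None:
        out["cox_risk_score"] = Xt[cox_coefficients.index].to_numpy() @ cox_coefficients.to_numpy()
    return out
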