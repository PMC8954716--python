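"""Multivariable logistic prediction of high-risk screening, evaluated by ROC.

Three pre-registered model specifications mirror the clinical question "can
the placenta triage women for postpartum screening?":

* ``clinical``  — delivery covariates only (maternal age, gestational weight
  gain, systolic and diastolic blood pressure at delivery, gestational age
  at delivery);
* ``mvm``       — the placental maternal-vascular-malperfusion severity
  score alone;
* ``combined``  — both sets.

Models are ordinary maximum-likelihood logistic regressions. Discrimination
is summarised by the in-sample (apparent) AUC, computed as the pairwise
concordance probability (Mann-Whitney identity, ties counted 1/2), with a
Hanley-McNeil confidence interval; sensitivity and specificity are reported
at the Youden-maximal operating point with Wilson score intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "CLINICAL_COVARIATES",
    "MVM_COVARIATES",
    "ModelSpec",
    "FittedModel",
    "RocResult",
    "default_model_specs",
    "fit_logistic",
    "roc_curve",
    "run_models",
]

CLINICAL_COVARIATES = (
    "maternal_age",
    "gestational_weight_gain",
    "sbp_delivery",
    "dbp_delivery",
    "ga_delivery",
)
MVM_COVARIATES = ("mvm_score",)

_SEPARATION_COEF = 15.0  # |log-odds| beyond this is clinically implausible


@dataclass(frozen=True)
class ModelSpec:
    """One pre-registered logistic model: outcome column plus covariates.

    An empty covariate tuple fits the intercept-only (null) model, whose
    intercept is the logit of the sample prevalence.
    """

    name: str
    outcome: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError(f"model {self.name!r}: duplicate covariates")


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: Mapping[str, float]  # includes "intercept"
    converged: bool
    separated: bool
    n_used: int
    linear_scores: np.ndarray  # per-used-participant linear predictor
    log_likelihood: float


@dataclass
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float  # percent, at the Youden-optimal threshold
    sensitivity_ci: tuple[float, float]
    specificity: float  # percent
    specificity_ci: tuple[float, float]
    threshold: float
    n_positive: int
    n_negative: int
    # empirical ROC coordinates (thresholds descending, including +/- inf ends)
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    thresholds: np.ndarray = field(repr=False, default=None)


def default_model_specs(
    outcome: str = "risk_group",
    bp_mode: str = "both",
) -> tuple[ModelSpec, ModelSpec, ModelSpec]:
    """The clinical / mvm / combined trio.

    ``bp_mode`` resolves the ambiguity of "blood pressure at delivery":
    ``"both"`` (default) enters systolic and diastolic separately,
    ``"systolic"`` drops diastolic, ``"map"`` uses the mean arterial
    pressure column ``map_delivery``.
    """
    if bp_mode == "both":
        bp: tuple[str, ...] = ("sbp_delivery", "dbp_delivery")
    elif bp_mode == "systolic":
        bp = ("sbp_delivery",)
    elif bp_mode == "map":
        bp = ("map_delivery",)
    else:
        raise ValueError(f"unknown bp_mode {bp_mode!r}")
    clinical = ("maternal_age", "gestational_weight_gain") + bp + ("ga_delivery",)
    return (
        ModelSpec("clinical", outcome, clinical),
        ModelSpec("mvm", outcome, MVM_COVARIATES),
        ModelSpec("combined", outcome, clinical + MVM_COVARIATES),
    )


def _outcome_bool(series: pd.Series) -> pd.Series:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        vals = set(series.dropna().unique())
        if vals <= {"high", "low"}:
            return series == "high"
        raise ValueError(f"cannot interpret outcome values {sorted(map(str, vals))}")
    return series.astype(bool)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Maximum-likelihood logistic fit of ``spec`` on complete cases.

    Newton-Raphson with coefficient tolerance 1e-8 and at most 100
    iterations; if the Hessian becomes singular (perfect separation), the
    fit is retried by BFGS and the model is flagged ``separated``. A
    rank-deficient design raises, naming the collinear columns.
    """
    missing_cols = [c for c in (spec.outcome, *spec.covariates) if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"model {spec.name!r}: cohort lacks columns {missing_cols}")
    sub = cohort[[spec.outcome, *spec.covariates]].dropna()
    y = _outcome_bool(sub[spec.outcome]).to_numpy(dtype=float)
    X = sub[list(spec.covariates)].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    names = ["intercept", *spec.covariates]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"model {spec.name!r}: rank-deficient design; collinear columns: "
            f"{_collinear_columns(X, names)}"
        )
    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=0)
        except (np.linalg.LinAlgError, Exception) as exc:  # singular Hessian at separation
            if not isinstance(exc, np.linalg.LinAlgError) and "Singular" not in str(exc):
                raise
            separated = True
            res = model.fit(method="bfgs", maxiter=500, disp=0)
        if any(issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning)) for w in caught):
            separated = True
    params = np.asarray(res.params, dtype=float)
    if np.max(np.abs(params)) > _SEPARATION_COEF:
        separated = True
    if separated:
        warnings.warn(
            f"model {spec.name!r}: (quasi-)separation detected; coefficients unreliable",
            UserWarning,
            stacklevel=2,
        )
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names, params)),
        converged=bool(res.mle_retvals.get("converged", True)),
        separated=separated,
        n_used=len(y),
        linear_scores=X @ params,
        log_likelihood=float(res.llf),
    )


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney identity: ties receive average ranks, i.e. count 1/2
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    conf_level: float = 0.95,
) -> RocResult:
    """Empirical ROC analysis of continuous scores against boolean labels.

    AUC is the pairwise concordance probability; its CI uses the
    Hanley-McNeil variance formula. The operating point maximises Youden's
    J = sensitivity + specificity - 1 (predict positive when score >=
    threshold); among ties the highest (most specific) threshold is kept.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    auc = _auc_rank(scores, labels)

    # Hanley-McNeil CI
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    z = stats.norm.ppf(0.5 + conf_level / 2)
    half = z * np.sqrt(max(var, 0.0))
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    # empirical ROC over unique thresholds, descending
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.where(np.diff(sorted_scores))[0], len(scores) - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(~sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]

    j = tpr - fpr  # Youden's J at each threshold
    best = int(np.argmax(j))  # argmax keeps the first (highest) threshold on ties
    sens = tpr[best]
    spec = 1 - fpr[best]
    threshold = thresholds[best]

    tp = int(round(sens * n_pos))
    tn = int(round(spec * n_neg))
    se_lo, se_hi = proportion_confint(tp, n_pos, alpha=1 - conf_level, method="wilson")
    sp_lo, sp_hi = proportion_confint(tn, n_neg, alpha=1 - conf_level, method="wilson")

    return RocResult(
        auc=float(auc),
        auc_ci_low=float(ci_low),
        auc_ci_high=float(ci_high),
        sensitivity=float(100 * sens),
        sensitivity_ci=(float(100 * se_lo), float(100 * se_hi)),
        specificity=float(100 * spec),
        specificity_ci=(float(100 * sp_lo), float(100 * sp_hi)),
        threshold=float(threshold),
        n_positive=n_pos,
        n_negative=n_neg,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )


def run_models(
    cohort: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
) -> dict[str, tuple[FittedModel, RocResult]]:
    """Fit the pre-registered model trio and evaluate each by ROC."""
    specs = tuple(specs) if specs is not None else default_model_specs()
    results: dict[str, tuple[FittedModel, RocResult]] = {}
    for spec in specs:
        fitted = fit_logistic(cohort, spec)
        sub = cohort[[spec.outcome, *spec.covariates]].dropna()
        labels = _outcome_bool(sub[spec.outcome]).to_numpy()
        results[spec.name] = (fitted, roc_curve(fitted.linear_scores, labels))
    return results
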