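"""Synthetic study cohorts with known ground truth.

No individual-level data were released by the study this pipeline
operationalises, so every stage is exercised on simulated cohorts whose
statistical structure matches the published summaries:

* lesion presence is Bernoulli per lesion with default prevalences equal to
  the pooled published frequencies (count / 85); grades given presence are
  uniform over the positive grades of the lesion's scale (configurable);
* the high-risk screening outcome is drawn from a logistic model whose
  severe-MVM coefficient is ``ln(target_or)`` (default OR 3.1), with weak
  standardized clinical-covariate effects and an intercept solved
  numerically so that the non-exposed high-risk rate equals
  ``baseline_highrisk_rate`` (default 0.51, the published low-exposure row);
* postpartum risk-factor measurements are back-filled *consistently with
  the drawn outcome*: a stratum pattern compatible with the outcome is
  sampled first, then measurements are drawn inside that stratum's
  threshold window, so re-screening the cohort reproduces the intended
  risk group by construction;
* delivery covariates are drawn from normal marginals matching the
  published combined-cohort summaries.

Identical parameters and seed give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import cvd_risk, lesion_scoring
from .cvd_risk import BOOLEAN_FACTORS, NUMERIC_FACTORS, RISK_FACTORS, Stratum
from .lesion_scoring import MVM_CATEGORY, ScoringScheme

__all__ = [
    "DEFAULT_LESION_PREVALENCES",
    "DEFAULT_CLINICAL_MARGINALS",
    "DEFAULT_CLINICAL_BETAS",
    "CohortParams",
    "SyntheticCohort",
    "generate",
    "fixture_small",
    "write_cohort",
    "read_cohort",
]

# Pooled published lesion frequencies (count / 85). Lesions never observed in
# the study default to 0; cap-completing form items absent from the published
# frequency table get small nominal rates.
DEFAULT_LESION_PREVALENCES: dict[str, float] = {
    "infarction": 23 / 85,
    "distal_villous_hypoplasia": 23 / 85,
    "accelerated_villous_maturation": 43 / 85,
    "syncytial_knots": 51 / 85,
    "perivillous_fibrin_deposition": 11 / 85,
    "villous_agglutination": 8 / 85,
    "retroplacental_hematoma": 2 / 85,
    "insufficient_vessel_remodeling": 9 / 85,
    "fibrinoid_necrosis": 6 / 85,
    "maternal_inflammatory_response": 6 / 85,
    "fetal_inflammatory_response": 4 / 85,
    "chorionic_vasculitis": 0.03,
    "subchorionitis": 0.05,
    "chorionic_plate_microabscesses": 0.01,
    "chorangiosis": 0.0,
    "chorangioma": 0.0,
    "delayed_villous_maturation": 3 / 85,
    "avascular_fibrotic_villi": 2 / 85,
    "thrombosis": 2 / 85,
    "intramural_fibrin_deposition": 3 / 85,
    "karyorrhexis": 0.0,
    "intervillous_thrombi": 6 / 85,
    "massive_perivillous_fibrin": 1 / 85,
    "maternal_floor_infarction": 0.0,
    "villitis_unknown_etiology": 8 / 85,
    "chronic_intervillositis": 0.0,
    "chronic_plasma_cell_deciduitis": 8 / 85,
    "eosinophilic_tcell_vasculitis": 0.01,
}

# Delivery covariates: (mean, sd, lower clip, upper clip). Means and sds from
# the published combined-cohort column; gestational age approximated by a
# clipped normal matched to the published median/IQR.
DEFAULT_CLINICAL_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "maternal_age": (31.9, 6.0, 16.0, 50.0),
    "gestational_weight_gain": (14.0, 7.1, -10.0, 40.0),
    "sbp_delivery": (152.0, 25.0, 90.0, 240.0),
    "dbp_delivery": (93.0, 13.0, 50.0, 150.0),
    "ga_delivery": (35.4, 4.3, 24.0, 42.0),
}

# Weak standardized (per-SD) log-odds effects of the delivery covariates on
# the high-risk outcome; the severe-MVM indicator carries the headline
# association.
DEFAULT_CLINICAL_BETAS: dict[str, float] = {
    "maternal_age": 0.05,
    "gestational_weight_gain": 0.05,
    "sbp_delivery": 0.10,
    "dbp_delivery": 0.05,
    "ga_delivery": -0.15,
}

# Plausible physiological windows used when back-filling measurements, so an
# unbounded top stratum still yields realistic values.
_PLAUSIBLE: dict[str, tuple[float, float]] = {
    "total_cholesterol": (3.0, 8.5),
    "systolic_bp": (90.0, 190.0),
    "diastolic_bp": (55.0, 120.0),
    "fasting_glucose": (3.8, 10.0),
}

_DECIMALS = {"total_cholesterol": 2, "systolic_bp": 1, "diastolic_bp": 1, "fasting_glucose": 2}


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth generating parameters for one synthetic cohort."""

    n: int = 85
    seed: int = 0
    target_or: float = 3.1
    baseline_highrisk_rate: float = 0.51
    mvm_threshold: int = 2
    lesion_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_PREVALENCES)
    )
    # per-lesion probabilities over positive grades 1..max_grade; lesions not
    # listed use the uniform default
    grade_distribution: Mapping[str, Sequence[float]] = field(default_factory=dict)
    clinical_marginals: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_MARGINALS)
    )
    clinical_betas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_BETAS)
    )
    # sd of an optional shared latent placental-dysfunction factor inducing
    # lesion co-occurrence on the logit scale; 0 = independent lesions
    lesion_cooccurrence_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.target_or <= 0:
            raise ValueError("target_or must be positive")
        if not 0 < self.baseline_highrisk_rate < 1:
            raise ValueError("baseline_highrisk_rate must be in (0, 1)")
        for lesion_id, p in self.lesion_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {lesion_id!r} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lesion_prevalences"] = dict(d["lesion_prevalences"])
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort table plus the parameters that produced it."""

    table: pd.DataFrame
    params: CohortParams
    solved_intercept: float

    @property
    def n(self) -> int:
        return len(self.table)

    def ground_truth(self) -> dict:
        gt = self.params.to_dict()
        gt["solved_intercept"] = self.solved_intercept
        gt["empirical_mvm_severe_rate"] = float(self.table["mvm_severe"].mean())
        gt["empirical_highrisk_rate"] = float((self.table["risk_group"] == "high").mean())
        return gt


def _sample_strata(
    rng: np.random.Generator,
    outcome: np.ndarray,
) -> np.ndarray:
    """Sample a 7-factor stratum matrix consistent with each outcome.

    Low-risk rows receive either all-optimal (risk 8) or >=1 not-optimal
    (risk 27) patterns; high-risk rows one of elevated-only (39), exactly
    one major (39) or two majors (50). Mixture weights are fixed so the
    fixture of four risk categories is well represented at any n.
    """
    n = len(outcome)
    n_numeric = len(NUMERIC_FACTORS)
    # column positions of the numeric factors within RISK_FACTORS (booleans
    # cannot carry not_optimal/elevated strata under the default rules)
    numeric_idx = np.array([RISK_FACTORS.index(f) for f in NUMERIC_FACTORS])
    strata = np.zeros((n, len(RISK_FACTORS)), dtype=np.int8)
    u = rng.random(n)
    pick_numeric_pos = rng.integers(0, n_numeric, size=n)
    pick_numeric = numeric_idx[pick_numeric_pos]
    pick_numeric2 = numeric_idx[
        (pick_numeric_pos + 1 + rng.integers(0, n_numeric - 1, size=n)) % n_numeric
    ]
    pick_any = rng.integers(0, len(RISK_FACTORS), size=n)
    pick_any2 = (pick_any + 1 + rng.integers(0, len(RISK_FACTORS) - 1, size=n)) % len(
        RISK_FACTORS
    )
    extra = rng.random(n) < 0.5  # add an extra not-optimal factor where harmless

    low = ~outcome
    # low risk: 40% all optimal, 60% >=1 not optimal
    not_opt = low & (u >= 0.40)
    strata[not_opt, pick_numeric[not_opt]] = Stratum.NOT_OPTIMAL
    both = not_opt & extra
    strata[both, pick_numeric2[both]] = Stratum.NOT_OPTIMAL

    high = outcome
    elevated = high & (u < 0.35)
    one_major = high & (u >= 0.35) & (u < 0.80)
    two_major = high & (u >= 0.80)
    strata[elevated, pick_numeric[elevated]] = Stratum.ELEVATED
    e_extra = elevated & extra
    strata[e_extra, pick_numeric2[e_extra]] = Stratum.NOT_OPTIMAL
    strata[one_major, pick_any[one_major]] = Stratum.MAJOR
    strata[two_major, pick_any[two_major]] = Stratum.MAJOR
    strata[two_major, pick_any2[two_major]] = Stratum.MAJOR
    return strata


def _backfill_measurements(
    rng: np.random.Generator,
    strata: np.ndarray,
    rules: cvd_risk.StratificationRules,
) -> dict[str, np.ndarray]:
    """Draw measurements inside each participant's assigned stratum window."""
    n = strata.shape[0]
    out: dict[str, np.ndarray] = {}
    for j, factor in enumerate(RISK_FACTORS):
        rule = rules.rule(factor)
        if factor in BOOLEAN_FACTORS:
            out[factor] = strata[:, j] == Stratum.MAJOR
            continue
        values = np.empty(n)
        dec = _DECIMALS[factor]
        pl_lo, pl_hi = _PLAUSIBLE[factor]
        for stratum in Stratum:
            mask = strata[:, j] == stratum
            if not mask.any():
                continue
            lo, hi = rule.interval(stratum)
            lo, hi = max(lo, pl_lo), min(hi, pl_hi)
            draw = rng.uniform(lo, hi, size=int(mask.sum()))
            # floor at the reported precision so rounding never crosses the
            # stratum's upper threshold
            values[mask] = np.floor(draw * 10**dec) / 10**dec
        out[factor] = values
    return out


def generate(
    params: CohortParams,
    scheme: Optional[ScoringScheme] = None,
    rules: Optional[cvd_risk.StratificationRules] = None,
) -> SyntheticCohort:
    """Generate one synthetic cohort under ``params``.

    Raises if the requested baseline high-risk rate is unreachable or if no
    participant is unexposed (the intercept is anchored on the non-exposed
    stratum).
    """
    scheme = scheme or lesion_scoring.default_scheme()
    rules = rules or cvd_risk.default_rules()
    rng = np.random.default_rng(params.seed)
    n = params.n

    # (1) lesion presence and grades
    latent = (
        rng.standard_normal(n) * params.lesion_cooccurrence_sd
        if params.lesion_cooccurrence_sd > 0
        else None
    )
    grades: dict[str, np.ndarray] = {}
    for lesion in scheme.lesions:
        p = float(params.lesion_prevalences.get(lesion.lesion_id, 0.0))
        if p <= 0:
            grades[lesion.lesion_id] = np.zeros(n, dtype=np.int64)
            continue
        if latent is not None:
            prob = expit(logit(min(p, 1 - 1e-12)) + latent)
        else:
            prob = p
        present = rng.random(n) < prob
        dist = params.grade_distribution.get(lesion.lesion_id)
        if dist is None:
            g = rng.integers(1, lesion.max_grade + 1, size=n)
        else:
            dist = np.asarray(dist, dtype=float)
            if len(dist) != lesion.max_grade or not np.isclose(dist.sum(), 1.0):
                raise ValueError(
                    f"grade distribution for {lesion.lesion_id!r} must have "
                    f"{lesion.max_grade} probabilities summing to 1"
                )
            g = rng.choice(np.arange(1, lesion.max_grade + 1), size=n, p=dist)
        grades[lesion.lesion_id] = np.where(present, g, 0)

    # (2) severity scores (same cap rule the scoring engine applies)
    category_scores: dict[str, np.ndarray] = {}
    for cat in scheme.categories:
        total = np.zeros(n, dtype=np.int64)
        for lesion_id in cat.member_lesions:
            total += grades[lesion_id]
        category_scores[cat.category_id] = np.minimum(total, cat.max_score)
    mvm_score = category_scores[MVM_CATEGORY]
    exposed = mvm_score >= params.mvm_threshold
    cumulative = np.sum(list(category_scores.values()), axis=0)

    # (5) delivery covariates (drawn before the outcome: they enter the model)
    clinical: dict[str, np.ndarray] = {}
    for name, (mean, sd, lo, hi) in params.clinical_marginals.items():
        clinical[name] = np.clip(rng.normal(mean, sd, size=n), lo, hi)

    # (3) outcome from the logistic exposure model
    eta_cov = np.zeros(n)
    for name, beta in params.clinical_betas.items():
        mean, sd, _, _ = params.clinical_marginals[name]
        eta_cov += beta * (clinical[name] - mean) / sd
    if exposed.all():
        raise RuntimeError("no unexposed participants: cannot anchor the baseline rate")
    eta0 = eta_cov[~exposed]
    target = params.baseline_highrisk_rate

    def gap(c: float) -> float:
        return float(expit(c + eta0).mean() - target)

    try:
        intercept = brentq(gap, -30.0, 30.0, xtol=1e-10)
    except ValueError as exc:
        raise RuntimeError(
            f"baseline high-risk rate {target} unreachable given covariate "
            f"effects (solver bracket failed: {exc})"
        ) from exc
    eta = intercept + eta_cov + np.log(params.target_or) * exposed
    outcome = rng.random(n) < expit(eta)

    # (4) back-fill postpartum measurements consistent with the outcome
    strata = _sample_strata(rng, outcome)
    measurements = _backfill_measurements(rng, strata, rules)
    n_major = (strata == Stratum.MAJOR).sum(axis=1)
    pct = np.where(
        n_major >= 2,
        50,
        np.where(
            n_major == 1,
            39,
            np.where(
                (strata == Stratum.ELEVATED).any(axis=1),
                39,
                np.where((strata == Stratum.NOT_OPTIMAL).any(axis=1), 27, 8),
            ),
        ),
    )

    table = pd.DataFrame({"participant_id": [f"P{i:06d}" for i in range(1, n + 1)]})
    for lesion_id, g in grades.items():
        table[f"lesion_{lesion_id}"] = g
    for name, values in clinical.items():
        table[name] = np.round(values, 2)
    for cat_id, scores in category_scores.items():
        table[f"score_{cat_id}"] = scores
    table["mvm_score"] = mvm_score
    table["mvm_severe"] = exposed
    table["cumulative_score"] = cumulative
    for factor in RISK_FACTORS:
        table[factor] = measurements[factor]
    table["lifetime_risk_percent"] = pct.astype(int)
    table["risk_group"] = np.where(pct >= 39, "high", "low")
    return SyntheticCohort(table=table, params=params, solved_intercept=float(intercept))


def fixture_small() -> SyntheticCohort:
    """A deterministic hand-set 12-participant cohort used across the tests.

    Covers every lesion category, all four lifetime-risk categories, both
    screening groups, an exactly-at-threshold MVM placenta, a
    zero-pathology placenta and one missing lesion assessment.
    """
    scheme = lesion_scoring.default_scheme()
    # hand-set, deliberately varied delivery covariates (one value per participant)
    clinical_values = {
        "maternal_age": (28.0, 31.5, 34.0, 26.5, 39.0, 30.0, 33.5, 29.0, 36.0, 32.5, 38.5, 27.5),
        "gestational_weight_gain": (12.0, 15.5, 9.0, 18.0, 14.5, 11.0, 16.5, 13.0, 20.0, 10.5, 8.0, 17.0),
        "sbp_delivery": (142.0, 155.0, 148.0, 172.0, 165.0, 138.0, 150.0, 160.0, 145.0, 152.0, 168.0, 140.0),
        "dbp_delivery": (88.0, 95.0, 90.0, 104.0, 100.0, 85.0, 92.0, 98.0, 89.0, 93.0, 102.0, 86.0),
        "ga_delivery": (38.0, 33.0, 37.5, 30.5, 34.0, 39.0, 36.5, 32.0, 37.0, 35.5, 31.5, 38.5),
    }
    optimal = {
        "total_cholesterol": 4.2,
        "systolic_bp": 110.0,
        "diastolic_bp": 72.0,
        "antihypertensive_use": False,
        "fasting_glucose": 4.9,
        "diabetes_diagnosis": False,
        "current_smoker": False,
    }

    rows = []

    def participant(pid, lesions=None, risk_overrides=None, clinical_overrides=None):
        idx = len(rows)
        row: dict[str, object] = {"participant_id": pid}
        for lesion in scheme.lesions:
            row[f"lesion_{lesion.lesion_id}"] = 0
        for lesion_id, grade in (lesions or {}).items():
            row[f"lesion_{lesion_id}"] = grade
        for name, values in clinical_values.items():
            row[name] = values[idx]
        row.update(clinical_overrides or {})
        row.update(optimal)
        row.update(risk_overrides or {})
        rows.append(row)

    participant("P001")  # zero pathology, all optimal -> risk 8
    participant(
        "P002",
        lesions={"accelerated_villous_maturation": 2},  # MVM exactly at threshold
        risk_overrides={"systolic_bp": 125.0},  # one not-optimal -> 27
        clinical_overrides={"ga_delivery": 33.0},
    )
    participant(
        "P003",
        lesions={"syncytial_knots": 1},  # MVM 1: below threshold
        risk_overrides={"total_cholesterol": 5.5},  # elevated -> 39
    )
    participant(
        "P004",
        lesions={
            "infarction": 3,
            "distal_villous_hypoplasia": 2,
            "syncytial_knots": 3,
            "perivillous_fibrin_deposition": 1,
        },
        risk_overrides={"current_smoker": True},  # one major -> 39
        clinical_overrides={"ga_delivery": 30.5, "sbp_delivery": 172.0},
    )
    participant(
        "P005",
        lesions={"insufficient_vessel_remodeling": 2, "fibrinoid_necrosis": 1},
        risk_overrides={"antihypertensive_use": True, "systolic_bp": 165.0},  # two major -> 50
    )
    participant(
        "P006",
        lesions={
            "maternal_inflammatory_response": 2,
            "fetal_inflammatory_response": 1,
            "subchorionitis": 1,
        },
    )  # chorioamnionitis, all optimal -> 8
    participant(
        "P007",
        lesions={"chorangiosis": 2, "delayed_villous_maturation": 1},
        risk_overrides={"fasting_glucose": 5.8},  # not optimal -> 27
    )
    participant(
        "P008",
        lesions={"avascular_fibrotic_villi": 2, "thrombosis": 1, "intramural_fibrin_deposition": 1},
        risk_overrides={"diastolic_bp": 92.0},  # elevated -> 39
    )
    participant(
        "P009",
        lesions={"intervillous_thrombi": 2, "massive_perivillous_fibrin": 1},
        risk_overrides={"diabetes_diagnosis": True},  # one major -> 39
    )
    participant(
        "P010",
        lesions={"villitis_unknown_etiology": 3, "chronic_plasma_cell_deciduitis": 1},
    )  # chronic inflammation, all optimal -> 8
    participant(
        "P011",
        lesions={"syncytial_knots": 2, "villous_agglutination": 1},
        risk_overrides={"current_smoker": True, "diabetes_diagnosis": True},  # -> 50
        clinical_overrides={"maternal_age": 38.5},
    )
    participant(
        "P012",
        lesions={"syncytial_knots": 1, "villitis_unknown_etiology": 1},
        risk_overrides={"total_cholesterol": 4.8},  # not optimal -> 27
    )

    table = pd.DataFrame(rows)
    # one missing lesion assessment (scored 0 downstream, flagged incomplete)
    table["lesion_karyorrhexis"] = table["lesion_karyorrhexis"].astype(float)
    table.loc[table["participant_id"] == "P010", "lesion_karyorrhexis"] = np.nan

    # derived columns mirroring generate()'s schema
    obs = lesion_scoring.read_observations_wide(table, scheme)
    profiles = {p.participant_id: p for p in lesion_scoring.profiles_for_cohort(obs, scheme)}
    for cat in scheme.categories:
        table[f"score_{cat.category_id}"] = [
            profiles[pid].category_scores[cat.category_id] for pid in table["participant_id"]
        ]
    table["mvm_score"] = table[f"score_{MVM_CATEGORY}"]
    table["mvm_severe"] = table["mvm_score"] >= 2
    table["cumulative_score"] = [
        profiles[pid].cumulative_score for pid in table["participant_id"]
    ]
    screened = cvd_risk.screen_cohort(table)
    table["lifetime_risk_percent"] = screened["lifetime_risk_percent"]
    table["risk_group"] = screened["risk_group"]
    params = CohortParams(n=len(table), seed=0)
    return SyntheticCohort(table=table, params=params, solved_intercept=float("nan"))


def write_cohort(cohort: SyntheticCohort, path: Union[str, Path], sidecar: bool = True) -> None:
    """Write the cohort table as CSV plus a ground-truth JSON sidecar."""
    path = Path(path)
    cohort.table.to_csv(path, index=False)
    if sidecar:
        gt = cohort.ground_truth()
        side = path.with_suffix(path.suffix + ".ground_truth.json")
        side.write_text(json.dumps(gt, indent=2, default=float) + "\n")


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (or user data)."""
    return pd.read_csv(path, sep=None, engine="python")
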