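"""Categorical lifetime cardiovascular risk from a postpartum risk-factor profile.

Seven risk factors measured at the 6-month postpartum screening visit —
total cholesterol, systolic and diastolic blood pressure, anti-hypertensive
use, fasting glucose, diabetes diagnosis, and current smoking — are each
stratified as optimal / not optimal / elevated / major against
protocol-defined thresholds. The categorical lifetime risk then follows
from the stratum counts, highest severity first:

========================  ==================
stratum pattern           lifetime risk (%)
========================  ==================
>= 2 factors major        50
exactly 1 factor major    39
>= 1 factor elevated      39
>= 1 factor not optimal   27
all factors optimal       8
========================  ==================

Risk is dichotomized at 39%: >= 39% screens high risk, < 39% low risk.
Threshold defaults live in ``data/default_risk_rules.yaml`` and are fully
user-editable.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

__all__ = [
    "RISK_FACTORS",
    "BOOLEAN_FACTORS",
    "NUMERIC_FACTORS",
    "Stratum",
    "RiskFactorProfile",
    "NumericFactorRule",
    "BooleanFactorRule",
    "StratificationRules",
    "LifetimeRiskResult",
    "RulesValidationError",
    "load_rules",
    "default_rules",
    "stratify_factor",
    "lifetime_risk",
    "dichotomize",
    "assess",
    "screen_cohort",
]

NUMERIC_FACTORS = ("total_cholesterol", "systolic_bp", "diastolic_bp", "fasting_glucose")
BOOLEAN_FACTORS = ("antihypertensive_use", "diabetes_diagnosis", "current_smoker")
RISK_FACTORS = (
    "total_cholesterol",
    "systolic_bp",
    "diastolic_bp",
    "antihypertensive_use",
    "fasting_glucose",
    "diabetes_diagnosis",
    "current_smoker",
)

RISK_CATEGORIES = (8, 27, 39, 50)


class RulesValidationError(ValueError):
    """A stratification rules file violates a structural invariant."""


class Stratum(enum.IntEnum):
    """Ordered severity stratum of a single risk factor."""

    OPTIMAL = 0
    NOT_OPTIMAL = 1
    ELEVATED = 2
    MAJOR = 3

    @classmethod
    def from_label(cls, label: str) -> "Stratum":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise RulesValidationError(f"unknown stratum label {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class RiskFactorProfile:
    """The seven screening measurements for one participant."""

    participant_id: str
    total_cholesterol: Optional[float]
    systolic_bp: Optional[float]
    diastolic_bp: Optional[float]
    antihypertensive_use: Optional[bool]
    fasting_glucose: Optional[float]
    diabetes_diagnosis: Optional[bool]
    current_smoker: Optional[bool]

    def value(self, factor_id: str):
        if factor_id not in RISK_FACTORS:
            raise KeyError(f"unknown risk factor {factor_id!r}")
        return getattr(self, factor_id)


@dataclass(frozen=True)
class NumericFactorRule:
    """Half-open intervals [lower, upper) mapping a measurement to a stratum."""

    factor_id: str
    uppers: tuple[Optional[float], ...]  # per-interval upper bound; None = unbounded
    strata: tuple[Stratum, ...]
    lo: float
    hi: float
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.uppers) != len(self.strata) or not self.strata:
            raise RulesValidationError(f"{self.factor_id}: malformed interval table")
        finite = [u for u in self.uppers if u is not None]
        if self.uppers[-1] is not None:
            raise RulesValidationError(f"{self.factor_id}: last interval must be unbounded")
        if any(u is None for u in self.uppers[:-1]):
            raise RulesValidationError(f"{self.factor_id}: only the last interval may be unbounded")
        if any(b >= c for b, c in zip(finite, finite[1:])):
            raise RulesValidationError(f"{self.factor_id}: interval bounds must be strictly increasing")

    def stratify(self, value: float) -> Stratum:
        if not self.lo <= value <= self.hi:
            raise ValueError(
                f"{self.factor_id}: value {value} outside admissible range "
                f"[{self.lo}, {self.hi}]"
            )
        for upper, stratum in zip(self.uppers, self.strata):
            if upper is None or value < upper:
                return stratum
        raise AssertionError("unreachable: last interval is unbounded")

    def interval(self, stratum: Stratum) -> tuple[float, float]:
        """The [lower, upper) measurement interval of a stratum, clipped to the
        admissible range. Used by the synthetic generator for back-filling."""
        lower = self.lo
        for upper, s in zip(self.uppers, self.strata):
            hi = self.hi if upper is None else min(upper, self.hi)
            if s == stratum:
                return (lower, hi)
            lower = hi
        raise KeyError(f"{self.factor_id}: no interval maps to stratum {stratum.label}")


@dataclass(frozen=True)
class BooleanFactorRule:
    factor_id: str
    when_false: Stratum
    when_true: Stratum

    def stratify(self, value: bool) -> Stratum:
        return self.when_true if value else self.when_false


@dataclass(frozen=True)
class StratificationRules:
    """Per-factor rules covering all seven risk factors."""

    factors: Mapping[str, Union[NumericFactorRule, BooleanFactorRule]]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        missing = [f for f in RISK_FACTORS if f not in self.factors]
        if missing:
            raise RulesValidationError(f"rules missing factor(s): {missing}")

    def rule(self, factor_id: str) -> Union[NumericFactorRule, BooleanFactorRule]:
        try:
            return self.factors[factor_id]
        except KeyError:
            raise KeyError(f"unknown risk factor {factor_id!r}") from None


@dataclass(frozen=True)
class LifetimeRiskResult:
    participant_id: str
    strata: Mapping[str, Stratum]
    lifetime_risk_percent: int
    risk_group: str  # "low" | "high"


def _build_rules(raw: Mapping) -> StratificationRules:
    if "factors" not in raw:
        raise RulesValidationError("rules file missing 'factors' block")
    factors: dict[str, Union[NumericFactorRule, BooleanFactorRule]] = {}
    for factor_id, entry in raw["factors"].items():
        kind = entry.get("kind")
        if kind == "numeric":
            lo, hi = entry.get("range", (float("-inf"), float("inf")))
            factors[factor_id] = NumericFactorRule(
                factor_id=factor_id,
                uppers=tuple(
                    None if iv["upper"] is None else float(iv["upper"])
                    for iv in entry["intervals"]
                ),
                strata=tuple(Stratum.from_label(iv["stratum"]) for iv in entry["intervals"]),
                lo=float(lo),
                hi=float(hi),
                units=str(entry.get("units", "")),
            )
        elif kind == "boolean":
            factors[factor_id] = BooleanFactorRule(
                factor_id=factor_id,
                when_false=Stratum.from_label(entry["when_false"]),
                when_true=Stratum.from_label(entry["when_true"]),
            )
        else:
            raise RulesValidationError(f"{factor_id}: kind must be 'numeric' or 'boolean'")
    return StratificationRules(factors=factors, version=str(raw.get("version", "unversioned")))


def load_rules(path: Union[str, Path]) -> StratificationRules:
    """Load and validate a stratification rules file (YAML)."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise RulesValidationError(f"cannot parse rules file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise RulesValidationError(f"rules file {path} is not a mapping")
    return _build_rules(raw)


def default_rules() -> StratificationRules:
    """The rules shipped with the package (Framingham lifetime-risk strata)."""
    ref = importlib.resources.files("pps.data") / "default_risk_rules.yaml"
    return _build_rules(yaml.safe_load(ref.read_text()))


def stratify_factor(
    factor_id: str,
    value: Union[float, bool],
    rules: StratificationRules,
) -> Stratum:
    """Map one measured value (or boolean status) to its stratum."""
    rule = rules.rule(factor_id)
    if isinstance(rule, BooleanFactorRule):
        if not isinstance(value, (bool,)) and value not in (0, 1):
            raise ValueError(f"{factor_id}: expected boolean, got {value!r}")
        return rule.stratify(bool(value))
    return rule.stratify(float(value))


def lifetime_risk(strata: Mapping[str, Stratum]) -> int:
    """Categorical lifetime risk (%) from the seven factor strata.

    Rules apply highest-severity first: >=2 major -> 50; exactly 1 major ->
    39; else >=1 elevated -> 39; else >=1 not optimal -> 27; else 8.
    """
    missing = [f for f in RISK_FACTORS if f not in strata]
    if missing:
        raise ValueError(f"missing stratum for factor(s): {missing}")
    values = [strata[f] for f in RISK_FACTORS]
    n_major = sum(s == Stratum.MAJOR for s in values)
    if n_major >= 2:
        return 50
    if n_major == 1:
        return 39
    if any(s == Stratum.ELEVATED for s in values):
        return 39
    if any(s == Stratum.NOT_OPTIMAL for s in values):
        return 27
    return 8


def dichotomize(lifetime_risk_percent: int) -> str:
    """Collapse the categorical risk into the clinic's low/high screen."""
    if lifetime_risk_percent not in RISK_CATEGORIES:
        raise ValueError(
            f"lifetime risk must be one of {RISK_CATEGORIES}, got {lifetime_risk_percent}"
        )
    return "high" if lifetime_risk_percent >= 39 else "low"


def assess(profile: RiskFactorProfile, rules: StratificationRules) -> LifetimeRiskResult:
    """Stratify all seven factors and return the categorical risk result."""
    strata = {}
    for factor_id in RISK_FACTORS:
        value = profile.value(factor_id)
        if value is None or (not isinstance(value, (bool,)) and pd.isna(value)):
            raise ValueError(
                f"participant {profile.participant_id!r}: missing measurement for "
                f"{factor_id!r}"
            )
        strata[factor_id] = stratify_factor(factor_id, value, rules)
    pct = lifetime_risk(strata)
    return LifetimeRiskResult(
        participant_id=profile.participant_id,
        strata=strata,
        lifetime_risk_percent=pct,
        risk_group=dichotomize(pct),
    )


def screen_cohort(
    cohort: pd.DataFrame,
    rules: Optional[StratificationRules] = None,
    missing: str = "error",
) -> pd.DataFrame:
    """Screen every participant, appending lifetime_risk_percent and risk_group.

    Parameters
    ----------
    cohort
        Table with a ``participant_id`` column and the seven risk-factor
        columns named as in :class:`RiskFactorProfile`.
    rules
        Stratification rules; package defaults if omitted.
    missing
        Policy for missing measurements: ``"error"`` (default — silent
        imputation is unsafe in a clinical screen), ``"impute_optimal"``
        (treat missing as optimal, flagged in ``risk_imputed``), or
        ``"exclude"`` (drop the participant).
    """
    if missing not in ("error", "impute_optimal", "exclude"):
        raise ValueError(f"unknown missing-data policy {missing!r}")
    rules = rules or default_rules()
    out = cohort.copy()
    pcts: list[Optional[int]] = []
    groups: list[Optional[str]] = []
    imputed: list[bool] = []
    keep: list[bool] = []
    for _, row in cohort.iterrows():
        pid = str(row["participant_id"])
        strata = {}
        was_imputed = False
        absent = [f for f in RISK_FACTORS if f not in row or pd.isna(row.get(f))]
        if absent:
            if missing == "error":
                raise ValueError(
                    f"participant {pid!r}: missing measurement(s) for {absent} "
                    "(set missing='impute_optimal' or 'exclude' to override)"
                )
            if missing == "exclude":
                keep.append(False)
                pcts.append(None)
                groups.append(None)
                imputed.append(False)
                continue
            was_imputed = True
        for factor_id in RISK_FACTORS:
            if factor_id in absent:
                strata[factor_id] = Stratum.OPTIMAL
            else:
                strata[factor_id] = stratify_factor(factor_id, row[factor_id], rules)
        pct = lifetime_risk(strata)
        keep.append(True)
        pcts.append(pct)
        groups.append(dichotomize(pct))
        imputed.append(was_imputed)
    out["lifetime_risk_percent"] = pcts
    out["risk_group"] = groups
    if missing == "impute_optimal":
        out["risk_imputed"] = imputed
    if missing == "exclude":
        out = out[pd.Series(keep, index=out.index)].copy()
        out["lifetime_risk_percent"] = out["lifetime_risk_percent"].astype(int)
    return out
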