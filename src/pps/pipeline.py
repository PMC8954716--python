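"""End-to-end orchestration: score -> risk -> associate -> predict -> report.

A run takes a cohort table (wide lesion columns plus delivery covariates and
postpartum measurements), scores every placenta against a scoring scheme,
screens every participant's lifetime cardiovascular risk, tests the
severe-MVM association with the high-risk screen, fits the prediction-model
trio, and emits a structured report: cohort descriptives, a published-style
lesion frequency table by risk group with per-row Pearson p-values, the 2x2
association, model results, and a provenance block (config hash, seed,
package version). The report is a pure function of (inputs, config): rerun
it and the JSON is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__, association_stats, cvd_risk, lesion_scoring, prediction_models
from .association_stats import ContingencyTable, _normalish
from .lesion_scoring import MVM_CATEGORY, ScoringScheme

__all__ = ["RunConfig", "run", "summarize_cohort", "lesion_frequency_table"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort: Union[str, Path, pd.DataFrame]
    scheme_path: Optional[Union[str, Path]] = None
    rules_path: Optional[Union[str, Path]] = None
    mvm_threshold: int = 2
    missing: str = "error"  # missing-measurement policy for risk screening
    bp_mode: str = "both"
    zero_cell: str = "undefined"
    chi2_correction: bool = False
    bh_adjust: bool = False  # extra: Benjamini-Hochberg column in the lesion table
    models: Optional[Sequence[str]] = ("clinical", "mvm", "combined")
    out_dir: Optional[Union[str, Path]] = None
    seed: int = 0

    def provenance_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = str(d["cohort"]) if not isinstance(self.cohort, pd.DataFrame) else "<in-memory>"
        d["scheme_path"] = str(d["scheme_path"]) if d["scheme_path"] else None
        d["rules_path"] = str(d["rules_path"]) if d["rules_path"] else None
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
        d["models"] = list(d["models"]) if d["models"] else None
        return d


def _round(x, nd=6):
    return None if x is None else round(float(x), nd)


def summarize_cohort(cohort: pd.DataFrame, variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-variable descriptives in the published style.

    Continuous variables report mean +/- SD when they pass the same
    Shapiro-Wilk gate the group comparisons use, otherwise median (IQR;
    linear-interpolation percentiles). Booleans and categoricals report
    n (%). All-missing columns are reported as such, never dropped.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if variables is None:
        variables = [c for c in cohort.columns if c != "participant_id"]
    rows = []
    n_total = len(cohort)
    for var in variables:
        col = cohort[var]
        nonmiss = col.dropna()
        if nonmiss.empty:
            rows.append({"variable": var, "kind": "all_missing", "n": 0, "display": "all missing"})
            continue
        if pd.api.types.is_bool_dtype(nonmiss) or nonmiss.dtype == object:
            if nonmiss.dtype == object:
                levels = nonmiss.value_counts()
                disp = "; ".join(f"{k}: {v} ({100 * v / n_total:.1f}%)" for k, v in levels.items())
                rows.append(
                    {"variable": var, "kind": "count_percent", "n": int(nonmiss.size), "display": disp}
                )
            else:
                count = int(nonmiss.sum())
                pct = 100 * count / n_total
                rows.append(
                    {
                        "variable": var,
                        "kind": "count_percent",
                        "n": int(nonmiss.size),
                        "count": count,
                        "percent": _round(pct, 1),
                        "display": f"{count} ({pct:.1f}%)",
                    }
                )
            continue
        values = nonmiss.to_numpy(dtype=float)
        if _normalish(values):
            mean, sd = float(np.mean(values)), float(np.std(values, ddof=1))
            rows.append(
                {
                    "variable": var,
                    "kind": "mean_sd",
                    "n": len(values),
                    "mean": _round(mean),
                    "sd": _round(sd),
                    "display": f"{mean:.1f} ± {sd:.1f}",
                }
            )
        else:
            med = float(np.percentile(values, 50))
            q1, q3 = (float(np.percentile(values, q)) for q in (25, 75))
            rows.append(
                {
                    "variable": var,
                    "kind": "median_iqr",
                    "n": len(values),
                    "median": _round(med),
                    "q1": _round(q1),
                    "q3": _round(q3),
                    "display": f"{med:.1f} ({q1:.1f}, {q3:.1f})",
                }
            )
    return pd.DataFrame(rows)


def lesion_frequency_table(
    cohort: pd.DataFrame,
    scheme: ScoringScheme,
    mvm_threshold: int = 2,
    chi2_correction: bool = False,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Published-style lesion frequency table by risk group.

    One row per lesion (presence = grade > 0) plus severe-MVM and
    MVM-score-0 rows, each with high/low counts, percentages, and the
    Pearson chi-square p-value. ``bh_adjust`` appends a Benjamini-Hochberg
    adjusted column (an addition over the unadjusted published analysis).
    """
    if "risk_group" not in cohort.columns:
        raise KeyError("cohort must carry a risk_group column (run the risk stage first)")
    high = cohort["risk_group"] == "high"
    n_high, n_low = int(high.sum()), int((~high).sum())

    def row_for(label: str, indicator: pd.Series) -> dict:
        a = int((indicator & high).sum())
        c = int((indicator & ~high).sum())
        table = ContingencyTable(a=a, b=n_high - a, c=c, d=n_low - c)
        stat, p = association_stats.pearson_chi2(table, correction=chi2_correction)
        return {
            "lesion": label,
            "high_risk_n": a,
            "high_risk_pct": _round(100 * a / n_high, 1) if n_high else None,
            "low_risk_n": c,
            "low_risk_pct": _round(100 * c / n_low, 1) if n_low else None,
            "chi2": _round(stat),
            "p_value": _round(p),
        }

    rows = []
    for lesion in scheme.lesions:
        col = f"lesion_{lesion.lesion_id}"
        if col not in cohort.columns:
            continue
        present = cohort[col].fillna(0) > 0
        rows.append(row_for(lesion.display_name, present))
    mvm_col = cohort["mvm_score"]
    rows.append(row_for(f"MVM score 0", mvm_col == 0))
    rows.append(row_for(f"MVM score {mvm_threshold} or more", mvm_col >= mvm_threshold))
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_bh"] = np.round(adj, 6)
    return out


def _score_stage(cohort: pd.DataFrame, scheme: ScoringScheme, mvm_threshold: int) -> pd.DataFrame:
    obs = lesion_scoring.read_observations_wide(cohort, scheme)
    profiles = lesion_scoring.profiles_for_cohort(obs, scheme, mvm_threshold)
    prof_df = lesion_scoring.profiles_to_frame(profiles)
    out = cohort.drop(
        columns=[c for c in cohort.columns if c.startswith("score_") or c in
                 ("mvm_score", "mvm_severe", "cumulative_score", "n_missing_lesions")],
        errors="ignore",
    )
    out = out.merge(prof_df, on="participant_id", how="left", validate="one_to_one")
    out["mvm_score"] = out[f"score_{MVM_CATEGORY}"]
    return out


def run(config: RunConfig) -> dict:
    """Execute all pipeline stages and return (and optionally write) the report."""
    if isinstance(config.cohort, pd.DataFrame):
        cohort = config.cohort.copy()
    else:
        cohort = pd.read_csv(config.cohort, sep=None, engine="python")
    scheme = (
        lesion_scoring.load_scheme(config.scheme_path)
        if config.scheme_path
        else lesion_scoring.default_scheme()
    )
    rules = (
        cvd_risk.load_rules(config.rules_path) if config.rules_path else cvd_risk.default_rules()
    )

    # stage: score
    cohort = _score_stage(cohort, scheme, config.mvm_threshold)

    # stage: risk
    cohort = cohort.drop(columns=["lifetime_risk_percent", "risk_group"], errors="ignore")
    cohort = cvd_risk.screen_cohort(cohort, rules, missing=config.missing)

    # stage: associate
    table = association_stats.build_2x2(cohort, "mvm_severe", _high(cohort))
    assoc = association_stats.associate(
        table, zero_cell=config.zero_cell, correction=config.chi2_correction
    )

    # stage: predict
    model_section: dict[str, dict] = {}
    if config.models:
        specs = [
            s
            for s in prediction_models.default_model_specs(bp_mode=config.bp_mode)
            if s.name in set(config.models)
        ]
        fitted = prediction_models.run_models(_with_high(cohort), specs)
        for name, (model, roc) in fitted.items():
            model_section[name] = {
                "covariates": list(model.spec.covariates),
                "coefficients": {k: _round(v) for k, v in model.coefficients.items()},
                "converged": model.converged,
                "separated": model.separated,
                "n_used": model.n_used,
                "auc": _round(roc.auc),
                "auc_ci": [_round(roc.auc_ci_low), _round(roc.auc_ci_high)],
                "sensitivity_pct": _round(roc.sensitivity, 1),
                "sensitivity_ci": [_round(v, 1) for v in roc.sensitivity_ci],
                "specificity_pct": _round(roc.specificity, 1),
                "specificity_ci": [_round(v, 1) for v in roc.specificity_ci],
                "youden_threshold": _round(roc.threshold),
            }

    summary = summarize_cohort(cohort.drop(columns=["high_risk"], errors="ignore"))
    lesion_table = lesion_frequency_table(
        cohort,
        scheme,
        mvm_threshold=config.mvm_threshold,
        chi2_correction=config.chi2_correction,
        bh_adjust=config.bh_adjust,
    )

    prov_src = json.dumps(config.provenance_dict(), sort_keys=True)
    report = {
        "n_participants": int(len(cohort)),
        "summary": summary.to_dict(orient="records"),
        "lesion_frequencies": lesion_table.to_dict(orient="records"),
        "association": {
            "exposure": f"MVM score >= {config.mvm_threshold}",
            "outcome": "high lifetime CVD risk screen",
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "odds_ratio": _round(assoc.odds_ratio),
            "odds_ratio_display": None if assoc.odds_ratio is None else f"{assoc.odds_ratio:.2f}",
            "ci95": [_round(assoc.ci_low), _round(assoc.ci_high)],
            "chi2": _round(assoc.chi2_statistic),
            "p_value": _round(assoc.p_value),
            "or_defined": assoc.or_defined,
        },
        "models": model_section,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "scheme_version": scheme.version,
            "rules_version": rules.version,
            "config_sha256": hashlib.sha256(prov_src.encode()).hexdigest(),
        },
    }

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        summary.to_csv(out_dir / "summary.csv", index=False)
        lesion_table.to_csv(out_dir / "lesion_frequencies.csv", index=False)
        cohort.to_csv(out_dir / "scored_cohort.csv", index=False)
    return report


def _high(cohort: pd.DataFrame) -> str:
    cohort["high_risk"] = cohort["risk_group"] == "high"
    return "high_risk"


def _with_high(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["risk_group"] = cohort["risk_group"]
    return out
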