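"""Scenario summaries, group statistics and per-patient text reports.

Covers the tabular outputs a clinic would look at: the scenario comparison
(counts and nearest-integer percentages of patients tested / diagnosed,
with two-sample proportion tests between scenarios), the characterization
of the four stepwise decision groups (means ± SD with one-way ANOVA for
continuous variables, counts with chi-square for categorical ones), and a
deterministic plain-text report for a single patient showing the simulated
CSF step and the testing recommendation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .catalog import GROUPS, catalog_by_name
from .cohort import Cohort
from .dsi import DSIResult
from .scenarios import ScenarioConfig, ScenarioOutcome


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class ScenarioSummary:
    scenario: str
    n_total: int
    n_tested: int
    pct_tested: int
    n_diagnosed: int
    pct_diagnosed: int
    accuracy_among_diagnosed: float


def summarize_scenarios(
    outcome_lists: dict[str, list[ScenarioOutcome]],
    labels: dict[str, str] | pd.Series,
) -> list[ScenarioSummary]:
    """Counts, nearest-integer percentages and accuracy per scenario.

    All scenarios must have been run on the same cohort.
    """
    labels = dict(labels)
    id_sets = {s: {o.patient_id for o in outs} for s, outs in outcome_lists.items()}
    first = next(iter(id_sets.values()))
    if any(ids != first for ids in id_sets.values()):
        raise ValueError("scenario outcome lists cover different cohorts")
    summaries = []
    for scenario, outs in outcome_lists.items():
        n = len(outs)
        n_tested = sum(o.csf_tested for o in outs)
        diagnosed = [o for o in outs if o.diagnosed]
        if diagnosed:
            acc = float(
                np.mean([labels[o.patient_id] == o.predicted for o in diagnosed])
            )
        else:
            acc = float("nan")
        summaries.append(
            ScenarioSummary(
                scenario=scenario,
                n_total=n,
                n_tested=n_tested,
                pct_tested=round_half_away(100 * n_tested / n),
                n_diagnosed=len(diagnosed),
                pct_diagnosed=round_half_away(100 * len(diagnosed) / n),
                accuracy_among_diagnosed=acc,
            )
        )
    return summaries


def summaries_to_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass
class ProportionTestResult:
    """Two-sample proportion test on the percentage-point scale."""

    diff: float  # 100 * (x1/n1 - x2/n2)
    ci_low: float
    ci_high: float
    z: float
    p: float


def two_sample_proportion_test(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> ProportionTestResult:
    """Difference in proportions, pooled-variance z (two-sided), Wald
    (unpooled) confidence interval; no continuity correction."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    pooled = (x1 + x2) / (n1 + n2)
    if 0 < pooled < 1:
        z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        z, p = float(z), float(p)
    else:
        z, p = 0.0, 1.0
    if diff == 0:
        z, p = 0.0, 1.0
    se_wald = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    zc = stats.norm.ppf(1 - alpha / 2)
    return ProportionTestResult(
        diff=100 * diff,
        ci_low=100 * (diff - zc * se_wald),
        ci_high=100 * (diff + zc * se_wald),
        z=z,
        p=p,
    )


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook one-way ANOVA F and p over ≥2 groups of observations."""
    usable = [np.asarray(g, dtype=float) for g in groups]
    usable = [g[~np.isnan(g)] for g in usable]
    usable = [g for g in usable if g.size >= 2]
    if len(usable) < 2:
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*usable)
    return float(f), float(p)


def group_characteristics(
    cohort: Cohort,
    outcomes: list[ScenarioOutcome],
    nocsf_eval: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Characterize the four stepwise decision groups (long format).

    One row per (variable, decision group) with n / mean / sd for
    continuous variables and count / pct for categorical ones, plus the
    across-group p-value (one-way ANOVA or chi-square) repeated per
    variable. ``nocsf_eval`` — the pre-CSF classifier evaluation with a
    ``patient_id`` column — adds the margin-to-second-DSI and the share
    with DSI for AD above 0.6.
    """
    if any(o.scenario != "A" for o in outcomes):
        raise ValueError("group characteristics require stepwise (A) outcomes")
    dg = {o.patient_id: o.decision_group for o in outcomes}
    df = cohort.data.copy()
    df["decision_group"] = df["patient_id"].astype(str).map(dg)
    if df["decision_group"].isna().any():
        raise ValueError("outcomes do not cover the whole cohort")
    if nocsf_eval is not None:
        ev = nocsf_eval.set_index(nocsf_eval["patient_id"].astype(str))
        df["margin_nocsf"] = df["patient_id"].astype(str).map(ev["margin"])
        df["auc_positive"] = (
            df["patient_id"].astype(str).map(ev["dsi_AD"]) > 0.6
        ).astype(float)

    specs = catalog_by_name(cohort.catalog)
    continuous = ["age"] + [f for f, s in specs.items() if s.kind == "continuous"]
    if nocsf_eval is not None:
        continuous += ["margin_nocsf"]
    categorical = ["sex", "apoe_e4", "diagnosis"]
    if nocsf_eval is not None:
        categorical += ["auc_positive"]

    rows = []
    group_ids = sorted(set(dg.values()))
    for var in continuous:
        per_group = [
            df.loc[df["decision_group"] == g, var].to_numpy(dtype=float)
            for g in group_ids
        ]
        _, p = one_way_anova(per_group)
        for g, vals in zip(group_ids, per_group):
            vals = vals[~np.isnan(vals)]
            rows.append(
                {
                    "variable": var, "kind": "continuous", "decision_group": g,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "count": np.nan, "pct": np.nan, "p_value": p,
                }
            )
    for var in categorical:
        sub = df[["decision_group", var]].dropna()
        if sub[var].nunique() > 1 and sub["decision_group"].nunique() > 1:
            table = pd.crosstab(sub["decision_group"], sub[var])
            _, p, _, _ = stats.chi2_contingency(table)
            p = float(p)
        else:
            p = float("nan")
        positive = {"sex": "F", "apoe_e4": 1.0, "auc_positive": 1.0}
        for g in group_ids:
            gsub = sub.loc[sub["decision_group"] == g, var]
            if var == "diagnosis":
                for label in GROUPS:
                    cnt = int((gsub == label).sum())
                    rows.append(
                        {
                            "variable": f"diagnosis_{label}", "kind": "categorical",
                            "decision_group": g, "n": int(gsub.size),
                            "mean": np.nan, "sd": np.nan, "count": cnt,
                            "pct": 100 * cnt / gsub.size if gsub.size else np.nan,
                            "p_value": p,
                        }
                    )
            else:
                cnt = int((gsub == positive[var]).sum())
                rows.append(
                    {
                        "variable": var, "kind": "categorical", "decision_group": g,
                        "n": int(gsub.size), "mean": np.nan, "sd": np.nan,
                        "count": cnt,
                        "pct": 100 * cnt / gsub.size if gsub.size else np.nan,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)


RECOMMEND_LINE = "CSF measurement is considered potentially useful"
NO_RECOMMEND_LINE = "CSF measurement is not expected to change the diagnosis"


def patient_report(
    nocsf_result: DSIResult,
    outcome: ScenarioOutcome,
    config: ScenarioConfig,
    csf_result: DSIResult | None = None,
) -> str:
    """Deterministic plain-text decision-support report for one patient.

    Shows the per-group DSI without CSF, the step-1 confidence, the two
    simulated-CSF confidences, the testing recommendation, and — if CSF was
    performed — the post-CSF classification.
    """
    lines = [
        f"Decision support report — patient {outcome.patient_id}",
        f"PCC threshold: {config.pcc_threshold:.2f}",
        "",
        "Disease State Index without CSF:",
    ]
    for g in GROUPS:
        marker = " <-- highest" if g == nocsf_result.predicted else ""
        lines.append(f"  {g:<8} {nocsf_result.totals[g]:.3f}{marker}")
    lines.append(
        f"Margin to second DSI: {nocsf_result.margin:.3f} "
        f"({nocsf_result.n_features_used} features used)"
    )
    lines.append(f"Step 1 PCC (no CSF): {outcome.pcc_step1:.3f}")
    if outcome.decision_group == 1:
        lines.append("Directly diagnosed: confidence sufficient without CSF.")
    else:
        lines.append("")
        lines.append("Simulated CSF:")
        lines.append(f"  AD-like profile: PCC {outcome.pcc_sim_positive:.3f}")
        lines.append(f"  Normal profile:  PCC {outcome.pcc_sim_negative:.3f}")
        hit = (
            outcome.pcc_sim_positive >= config.pcc_threshold
            or outcome.pcc_sim_negative >= config.pcc_threshold
        )
        lines.append(RECOMMEND_LINE if hit else NO_RECOMMEND_LINE)
    if outcome.csf_tested:
        lines.append("")
        lines.append("After actual CSF:")
        if csf_result is not None:
            for g in GROUPS:
                marker = " <-- highest" if g == csf_result.predicted else ""
                lines.append(f"  {g:<8} {csf_result.totals[g]:.3f}{marker}")
        lines.append(f"  Final PCC: {outcome.pcc_final:.3f}")
        lines.append(
            f"  Suggested diagnosis: {outcome.predicted} "
            f"({'sufficient' if outcome.diagnosed else 'insufficient'} confidence)"
        )
    if outcome.decision_group is not None:
        lines.append("")
        lines.append(f"Decision group: {outcome.decision_group}")
    return "\n".join(lines) + "\n"
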