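"""Diagnostic scenarios for CSF test ordering.

Four policies decide which memory-clinic patients receive CSF biomarker
testing before a diagnosis is accepted (a diagnosis counts once the
personalized confidence PCC reaches a threshold, 0.80 by default):

* **A — computerized decision support** (stepwise). Step 1: classify from
  neuropsychology, MRI and APOE only; if PCC already reaches the threshold
  the patient is *directly diagnosed* (decision group 1) and no CSF is
  ordered. Step 2: otherwise substitute simulated CSF profiles — an
  "AD-like" positive profile (median corrected AB42/tau/p-tau of the AD
  reference group) and a "normal" negative profile (medians of the control
  group) — and recompute PCC under the with-CSF models. If neither
  simulation reaches the threshold, CSF is predicted unhelpful (group 2,
  untested). Step 3: otherwise actual CSF values are added; the final PCC
  decides group 3 (diagnosed after CSF) vs group 4 (tested, undiagnosed —
  suggestive of mixed pathology).
* **B — no CSF**: everyone assessed from the pre-CSF subset only.
* **C — appropriate-use criteria**: CSF ordered for patients with a
  pre-CSF total DSI for AD above 0.6.
* **D — CSF for all**.

Simulated profiles always overwrite the three analytes together, on the
age/sex-corrected scale, so the substituted values are coherent profiles
rather than per-analyte patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CSF_FEATURES
from .cohort import Cohort
from .dsi import DEFAULT_MIN_REF, DiseaseStateIndexClassifier
from .pcc import PCCModel, estimate_pcc_batch

SCENARIOS = ("A", "B", "C", "D")
TRIGGERS = ("positive_only", "negative_only", "both", "none", "n/a")


@dataclass(frozen=True)
class CSFProfile:
    """One simulated CSF profile on the corrected scale (pg/ml)."""

    ab42: float
    total_tau: float
    p_tau: float
    polarity: str  # "positive" (AD-like) or "negative" (normal)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        for name in CSF_FEATURES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} in CSF profile")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CSF_FEATURES}


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "A"
    pcc_threshold: float = 0.80
    auc_dsi_ad_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.pcc_threshold <= 1 and 0 < self.auc_dsi_ad_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class ScenarioOutcome:
    """Per-patient result of one scenario run."""

    patient_id: str
    scenario: str
    csf_tested: bool
    pcc_step1: float
    pcc_sim_positive: float | None
    pcc_sim_negative: float | None
    trigger: str
    pcc_final: float
    predicted: str
    diagnosed: bool
    decision_group: int | None  # 1-4, scenario A only


def derive_simulated_csf_profiles(
    reference: Cohort, min_ref: int = DEFAULT_MIN_REF
) -> tuple[CSFProfile, CSFProfile]:
    """Positive (AD medians) and negative (control medians) CSF profiles.

    Medians are taken per analyte over the reference group's corrected
    values; the positive profile always comes from the AD group and the
    negative profile from the controls, never mixed.
    """
    if not reference.corrected:
        raise ValueError("reference cohort must be covariate-corrected first")

    def medians(group: str) -> dict[str, float]:
        rows = reference.data.loc[reference.data["diagnosis"] == group]
        out = {}
        for name in CSF_FEATURES:
            vals = rows[name].dropna().to_numpy(dtype=float)
            if vals.size < min_ref:
                raise ValueError(
                    f"group {group}: only {vals.size} observed {name} values "
                    f"(< {min_ref}) for profile derivation"
                )
            out[name] = float(np.median(vals))
        return out

    pos = medians("AD")
    neg = medians("CONTROL")
    return (
        CSFProfile(**pos, polarity="positive"),
        CSFProfile(**neg, polarity="negative"),
    )


@dataclass
class _Precomputed:
    """Shared per-cohort quantities the four scenarios branch on."""

    ids: np.ndarray
    labels: np.ndarray | None
    pcc_step1: np.ndarray
    pred_step1: np.ndarray
    dsi_ad_nocsf: np.ndarray
    pcc_sim_pos: np.ndarray
    pcc_sim_neg: np.ndarray
    pcc_actual: np.ndarray
    pred_actual: np.ndarray
    missing_csf: list[list[str]] = field(default_factory=list)


def _precompute(
    cohort: Cohort,
    dsi_nocsf: DiseaseStateIndexClassifier,
    dsi_csf: DiseaseStateIndexClassifier,
    pcc_nocsf: PCCModel,
    pcc_csf: PCCModel,
    profiles: tuple[CSFProfile, CSFProfile],
) -> _Precomputed:
    if not cohort.corrected:
        raise ValueError("cohort must be covariate-corrected first")
    positive, negative = profiles
    if positive.polarity != "positive" or negative.polarity != "negative":
        raise ValueError("profiles must be (positive, negative)")
    X = cohort.data[list(cohort.feature_names)]

    res1 = dsi_nocsf.evaluate(X)
    pcc1, _ = estimate_pcc_batch(
        pcc_nocsf, res1["d1"].to_numpy(), res1["margin"].to_numpy()
    )

    def with_profile(profile: CSFProfile) -> np.ndarray:
        Xs = X.copy()
        for name, value in profile.as_dict().items():
            Xs[name] = value  # all three analytes overwritten together
        r = dsi_csf.evaluate(Xs)
        v, _ = estimate_pcc_batch(pcc_csf, r["d1"].to_numpy(), r["margin"].to_numpy())
        return v

    pcc_pos = with_profile(positive)
    pcc_neg = with_profile(negative)

    res_act = dsi_csf.evaluate(X)
    pcc_act, _ = estimate_pcc_batch(
        pcc_csf, res_act["d1"].to_numpy(), res_act["margin"].to_numpy()
    )

    labels = cohort.data["diagnosis"]
    if set(CSF_FEATURES) <= set(X.columns):
        csf_mat = X[list(CSF_FEATURES)].to_numpy(dtype=float)
        missing = [
            [name for name, v in zip(CSF_FEATURES, row) if np.isnan(v)]
            for row in csf_mat
        ]
    else:
        missing = [list(CSF_FEATURES)] * len(X)
    return _Precomputed(
        ids=cohort.data["patient_id"].astype(str).to_numpy(dtype=object),
        labels=None if labels.isna().all() else labels.to_numpy(dtype=object),
        pcc_step1=pcc1,
        pred_step1=res1["predicted"].to_numpy(),
        dsi_ad_nocsf=res1["dsi_AD"].to_numpy(),
        pcc_sim_pos=pcc_pos,
        pcc_sim_neg=pcc_neg,
        pcc_actual=pcc_act,
        pred_actual=res_act["predicted"].to_numpy(),
        missing_csf=missing,
    )


def _require_csf(pre: _Precomputed, i: int) -> None:
    if pre.missing_csf[i]:
        raise ValueError(
            f"patient {pre.ids[i]}: actual CSF required but "
            f"{pre.missing_csf[i][0]} is missing"
        )


def _outcomes_from_precomputed(
    pre: _Precomputed, config: ScenarioConfig
) -> list[ScenarioOutcome]:
    thr = config.pcc_threshold
    out: list[ScenarioOutcome] = []
    for i, pid in enumerate(pre.ids):
        pcc1 = float(pre.pcc_step1[i])
        if config.scenario == "A":
            if pcc1 >= thr:
                out.append(
                    ScenarioOutcome(pid, "A", False, pcc1, None, None, "n/a",
                                    pcc1, str(pre.pred_step1[i]), True, 1)
                )
                continue
            p_pos = float(pre.pcc_sim_pos[i])
            p_neg = float(pre.pcc_sim_neg[i])
            pos_hit, neg_hit = p_pos >= thr, p_neg >= thr
            if pos_hit and neg_hit:
                trigger = "both"
            elif pos_hit:
                trigger = "positive_only"
            elif neg_hit:
                trigger = "negative_only"
            else:
                trigger = "none"
            if trigger == "none":
                out.append(
                    ScenarioOutcome(pid, "A", False, pcc1, p_pos, p_neg, "none",
                                    pcc1, str(pre.pred_step1[i]), False, 2)
                )
                continue
            _require_csf(pre, i)
            p_act = float(pre.pcc_actual[i])
            diagnosed = p_act >= thr
            out.append(
                ScenarioOutcome(pid, "A", True, pcc1, p_pos, p_neg, trigger,
                                p_act, str(pre.pred_actual[i]), diagnosed,
                                3 if diagnosed else 4)
            )
        elif config.scenario == "B":
            out.append(
                ScenarioOutcome(pid, "B", False, pcc1, None, None, "n/a",
                                pcc1, str(pre.pred_step1[i]), pcc1 >= thr, None)
            )
        elif config.scenario == "C":
            if pre.dsi_ad_nocsf[i] > config.auc_dsi_ad_threshold:
                _require_csf(pre, i)
                p_act = float(pre.pcc_actual[i])
                out.append(
                    ScenarioOutcome(pid, "C", True, pcc1, None, None, "n/a",
                                    p_act, str(pre.pred_actual[i]), p_act >= thr, None)
                )
            else:
                out.append(
                    ScenarioOutcome(pid, "C", False, pcc1, None, None, "n/a",
                                    pcc1, str(pre.pred_step1[i]), pcc1 >= thr, None)
                )
        else:  # D: CSF for everyone; missing analytes tolerated, flagged
            p_act = float(pre.pcc_actual[i])
            out.append(
                ScenarioOutcome(pid, "D", True, pcc1, None, None, "n/a",
                                p_act, str(pre.pred_actual[i]), p_act >= thr, None)
            )
    return out


def run_scenario(
    cohort: Cohort,
    dsi_nocsf: DiseaseStateIndexClassifier,
    dsi_csf: DiseaseStateIndexClassifier,
    pcc_nocsf: PCCModel,
    pcc_csf: PCCModel,
    profiles: tuple[CSFProfile, CSFProfile],
    config: ScenarioConfig,
) -> list[ScenarioOutcome]:
    """Run one diagnostic scenario over a corrected cohort."""
    pre = _precompute(cohort, dsi_nocsf, dsi_csf, pcc_nocsf, pcc_csf, profiles)
    return _outcomes_from_precomputed(pre, config)


def run_all_scenarios(
    cohort: Cohort,
    dsi_nocsf: DiseaseStateIndexClassifier,
    dsi_csf: DiseaseStateIndexClassifier,
    pcc_nocsf: PCCModel,
    pcc_csf: PCCModel,
    profiles: tuple[CSFProfile, CSFProfile],
    pcc_threshold: float = 0.80,
    auc_dsi_ad_threshold: float = 0.6,
) -> dict[str, list[ScenarioOutcome]]:
    """All four scenarios, sharing one pass of model evaluations."""
    pre = _precompute(cohort, dsi_nocsf, dsi_csf, pcc_nocsf, pcc_csf, profiles)
    return {
        s: _outcomes_from_precomputed(
            pre,
            ScenarioConfig(
                scenario=s,
                pcc_threshold=pcc_threshold,
                auc_dsi_ad_threshold=auc_dsi_ad_threshold,
            ),
        )
        for s in SCENARIOS
    }


def pcc_cutoff_sweep(
    cohort: Cohort,
    dsi_nocsf: DiseaseStateIndexClassifier,
    dsi_csf: DiseaseStateIndexClassifier,
    pcc_nocsf: PCCModel,
    pcc_csf: PCCModel,
    profiles: tuple[CSFProfile, CSFProfile],
    cutoffs=None,
    auc_dsi_ad_threshold: float = 0.6,
) -> pd.DataFrame:
    """Share tested / diagnosed and accuracy among diagnosed over a grid of
    PCC cutoffs, for all four scenarios."""
    if cutoffs is None:
        cutoffs = np.arange(0.50, 1.0001, 0.05)
    cutoffs = np.minimum(np.asarray(cutoffs, dtype=float), 1.0)  # grid round-off
    pre = _precompute(cohort, dsi_nocsf, dsi_csf, pcc_nocsf, pcc_csf, profiles)
    if pre.labels is None:
        raise ValueError("cutoff sweep requires a labeled cohort")
    rows = []
    for cutoff in np.asarray(cutoffs, dtype=float):
        for s in SCENARIOS:
            cfg = ScenarioConfig(
                scenario=s,
                pcc_threshold=float(cutoff),
                auc_dsi_ad_threshold=auc_dsi_ad_threshold,
            )
            outcomes = _outcomes_from_precomputed(pre, cfg)
            tested = np.array([o.csf_tested for o in outcomes])
            diagnosed = np.array([o.diagnosed for o in outcomes])
            predicted = np.array([o.predicted for o in outcomes], dtype=object)
            n = len(outcomes)
            if diagnosed.any():
                acc = float(
                    (predicted[diagnosed] == pre.labels[diagnosed]).mean()
                )
            else:
                acc = np.nan
            rows.append(
                {
                    "cutoff": float(cutoff),
                    "scenario": s,
                    "share_tested": tested.mean(),
                    "share_diagnosed": diagnosed.mean(),
                    "accuracy_among_diagnosed": acc,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def outcomes_to_frame(outcomes: list[ScenarioOutcome]) -> pd.DataFrame:
    """One row per patient per scenario, in the outcome CSV schema."""
    return pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in outcomes],
            "scenario": [o.scenario for o in outcomes],
            "csf_tested": [o.csf_tested for o in outcomes],
            "pcc_step1": [o.pcc_step1 for o in outcomes],
            "pcc_sim_positive": np.array(
                [np.nan if o.pcc_sim_positive is None else o.pcc_sim_positive
                 for o in outcomes], dtype=float,
            ),
            "pcc_sim_negative": np.array(
                [np.nan if o.pcc_sim_negative is None else o.pcc_sim_negative
                 for o in outcomes], dtype=float,
            ),
            "trigger": [o.trigger for o in outcomes],
            "pcc_final": [o.pcc_final for o in outcomes],
            "predicted": [o.predicted for o in outcomes],
            "diagnosed": [o.diagnosed for o in outcomes],
            "decision_group": pd.array(
                [o.decision_group for o in outcomes], dtype="Int64"
            ),
        }
    )
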