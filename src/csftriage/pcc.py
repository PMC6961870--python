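"""Probability of correct class (PCC).

A high top DSI, or a wide margin between the two most similar diagnostic
groups, warrants more diagnostic confidence than a low value or a narrow
margin. PCC turns this into a personalized accuracy estimate: for a patient
classified at coordinates ``(d1, delta)`` — top total DSI and margin to the
second — it reports the share of correctly classified reference cases whose
own coordinates lie nearby. A patient with top DSI 0.75 and second DSI 0.67
is scored by the reference cases with DSI close to 0.75 and margin close to
0.08.

Reference coordinates are produced by leave-one-out refits of the DSI
classifier (each reference case is classified by a model that has never
seen it), "nearby" is the k nearest reference points in Euclidean distance
on the z-standardized (d1, delta) plane with ties at the k-th distance
included, and k defaults to ``max(20, ceil(0.1 * N))``. One PCC model is
built per feature subset (with / without CSF), since adding CSF changes the
geometry of the reference cloud.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalog import CANONICAL_PAIRS, GROUPS
from .cohort import Cohort
from .dsi import (
    DEFAULT_MIN_REF,
    DiseaseStateIndexClassifier,
    PairFeatureFit,
    _fit_pair_feature,
)


def default_k(n_points: int) -> int:
    return max(20, math.ceil(0.1 * n_points))


@dataclass
class PCCModel:
    """Leave-one-out reference points supporting neighborhood queries."""

    d1: np.ndarray
    delta: np.ndarray
    correct: np.ndarray  # bool
    k: int
    mean: np.ndarray  # standardization mean of (d1, delta)
    sd: np.ndarray  # standardization SD of (d1, delta)
    feature_subset: tuple[str, ...]
    patient_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.d1.size


@dataclass
class PCCEstimate:
    value: float
    n_neighbors: int
    d1: float
    delta: float


# -- scalar DSI evaluation with per-pair model overrides -------------------


def _pairwise_scalar(fits: dict[str, PairFeatureFit], row: dict[str, float]) -> float:
    num = den = 0.0
    cnt = 0
    for f, pf in fits.items():
        x = row.get(f)
        if x is None or np.isnan(x):
            continue
        cnt += 1
        if pf.relevance > 0:
            num += pf.relevance * pf.fitness(x)
            den += pf.relevance
    if cnt == 0:
        return float("nan")
    if den == 0:
        return 0.5
    return num / den


def _classify_scalar(
    pair_models: dict, row: dict[str, float]
) -> tuple[str, float, float]:
    """(predicted, d1, delta) for one record under the given pair models."""
    pw = {pair: _pairwise_scalar(fits, row) for pair, fits in pair_models.items()}
    totals = []
    for g in GROUPS:
        vals = []
        for other in GROUPS:
            if other == g:
                continue
            v = pw.get((g, other))
            if v is None:
                v = 1.0 - pw[(other, g)]
            if not np.isnan(v):
                vals.append(v)
        totals.append(np.mean(vals) if vals else np.nan)
    totals = np.asarray(totals)
    if np.isnan(totals).all():
        raise ValueError("no pairwise DSI defined for any group")
    order = np.where(np.isnan(totals), -np.inf, totals)
    best = int(np.argmax(order))
    d_sorted = np.sort(order)[::-1]
    d1 = d_sorted[0]
    d2 = d_sorted[1] if np.isfinite(d_sorted[1]) else 0.0
    return GROUPS[best], float(d1), float(d1 - d2)


def build_pcc_model(
    reference: Cohort,
    feature_subset=None,
    k: int | None = None,
    min_ref: int = DEFAULT_MIN_REF,
) -> PCCModel:
    """Build the PCC reference cloud by leave-one-out refitting.

    For each reference case, the DSI classifier is refitted without it (only
    the pairwise comparisons involving the case's own group change), the
    case is classified, and ``(d1, delta, correct)`` is recorded.
    """
    if not reference.corrected:
        raise ValueError("reference cohort must be covariate-corrected first")
    y = reference.data["diagnosis"]
    if y.isna().any():
        raise ValueError("reference cohort must be fully labeled")
    y = y.to_numpy(dtype=object)
    sizes = {g: int((y == g).sum()) for g in GROUPS}
    for g, n_g in sizes.items():
        if n_g < min_ref + 1:
            raise ValueError(
                f"group {g} has {n_g} members; leave-one-out needs at least "
                f"min_ref+1 = {min_ref + 1}"
            )

    full = DiseaseStateIndexClassifier(feature_subset=feature_subset, min_ref=min_ref)
    X = reference.data[list(reference.feature_names)]
    full.fit(X, y)
    feats = full.feature_names_
    cols = {f: X[f].to_numpy(dtype=float) for f in feats}
    group_idx = {g: np.flatnonzero(y == g) for g in GROUPS}
    # per (group, feature): sorted observed reference values
    group_sorted = {
        g: {f: np.sort(cols[f][idx][~np.isnan(cols[f][idx])]) for f in feats}
        for g, idx in group_idx.items()
    }

    n = len(X)
    d1 = np.empty(n)
    delta = np.empty(n)
    correct = np.empty(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            g = y[i]
            row = {f: cols[f][i] for f in feats}
            loo_models: dict = {}
            for pair in CANONICAL_PAIRS:
                if g not in pair:
                    loo_models[pair] = full.pair_models_[pair]
                    continue
                other = pair[0] if pair[1] == g else pair[1]
                fits: dict[str, PairFeatureFit] = {}
                for f in feats:
                    own = group_sorted[g][f]
                    x = row[f]
                    if np.isnan(x):
                        reduced = own
                    else:
                        pos_at = np.searchsorted(own, x)
                        reduced = np.delete(own, pos_at)
                    theirs = group_sorted[other][f]
                    if reduced.size < min_ref or theirs.size < min_ref:
                        continue
                    if pair[0] == g:
                        fits[f] = _fit_pair_feature(reduced, theirs, feature=f, pair=pair)
                    else:
                        fits[f] = _fit_pair_feature(theirs, reduced, feature=f, pair=pair)
                loo_models[pair] = fits
            pred, d1_i, delta_i = _classify_scalar(loo_models, row)
            d1[i] = d1_i
            delta[i] = delta_i
            correct[i] = pred == g

    coords = np.column_stack([d1, delta])
    sd = coords.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return PCCModel(
        d1=d1,
        delta=delta,
        correct=correct,
        k=k if k is not None else default_k(n),
        mean=coords.mean(axis=0),
        sd=sd,
        feature_subset=feats,
        patient_ids=tuple(reference.data["patient_id"].astype(str)),
    )


# -- queries ---------------------------------------------------------------


def estimate_pcc_batch(model: PCCModel, d1, delta) -> tuple[np.ndarray, np.ndarray]:
    """PCC values (and neighbor counts) for arrays of query coordinates."""
    d1 = np.atleast_1d(np.asarray(d1, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    if ((d1 < 0) | (d1 > 1) | (delta < 0) | (delta > d1)).any():
        raise ValueError("query must satisfy 0 <= delta <= d1 <= 1")
    zq = (np.column_stack([d1, delta]) - model.mean) / model.sd
    zp = (np.column_stack([model.d1, model.delta]) - model.mean) / model.sd
    # squared Euclidean distances, queries x reference points
    dist = ((zq[:, None, :] - zp[None, :, :]) ** 2).sum(axis=2)
    k = min(model.k, model.n)
    kth = np.partition(dist, k - 1, axis=1)[:, k - 1]
    mask = dist <= kth[:, None]  # ties at the k-th distance included
    n_nb = mask.sum(axis=1)
    values = (mask & model.correct[None, :]).sum(axis=1) / n_nb
    return values, n_nb


def estimate_pcc(model: PCCModel, d1: float, delta: float) -> PCCEstimate:
    """PCC at one (top DSI, margin) query point."""
    values, n_nb = estimate_pcc_batch(model, [d1], [delta])
    return PCCEstimate(
        value=float(values[0]), n_neighbors=int(n_nb[0]), d1=float(d1), delta=float(delta)
    )


def calibration_report(
    model: PCCModel,
    eval_cohort: Cohort,
    dsi: DiseaseStateIndexClassifier,
    bins: int = 10,
) -> pd.DataFrame:
    """Bin evaluation patients by estimated PCC and compare the bin-mean PCC
    with the empirical share of correct predictions.

    Bins are equal-width on [0, 1]; empty bins are reported with n = 0.
    Evaluating on the model's own reference is allowed but flagged as
    optimistic with a warning.
    """
    if not eval_cohort.corrected:
        raise ValueError("evaluation cohort must be covariate-corrected first")
    labels = eval_cohort.data["diagnosis"]
    if labels.isna().any():
        raise ValueError("evaluation cohort must be labeled")
    ids = set(eval_cohort.data["patient_id"].astype(str))
    if ids & set(model.patient_ids):
        warnings.warn(
            "evaluation cohort overlaps the PCC reference; accuracy is optimistic",
            stacklevel=2,
        )
    res = dsi.evaluate(eval_cohort.data[list(eval_cohort.feature_names)])
    pcc, _ = estimate_pcc_batch(model, res["d1"].to_numpy(), res["margin"].to_numpy())
    acc = (res["predicted"].to_numpy() == labels.to_numpy(dtype=object)).astype(float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(pcc, edges[1:-1], right=False), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        n_b = int(sel.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_pcc": float(pcc[sel].mean()) if n_b else np.nan,
                "accuracy": float(acc[sel].mean()) if n_b else np.nan,
                "n": n_b,
            }
        )
    return pd.DataFrame(rows)


# -- sklearn-style wrapper -------------------------------------------------


class ProbabilityOfCorrectClass(BaseEstimator):
    """Estimator wrapper: fit builds the leave-one-out PCC reference from a
    feature frame and labels; predict returns per-row PCC values.

    Attributes
    ----------
    dsi_ : DiseaseStateIndexClassifier
        Full-reference DSI classifier (used to classify new patients).
    model_ : PCCModel
        Leave-one-out reference cloud.
    """

    def __init__(self, feature_subset=None, k: int | None = None, min_ref: int = DEFAULT_MIN_REF):
        self.feature_subset = feature_subset
        self.k = k
        self.min_ref = min_ref

    def fit(self, X: pd.DataFrame, y, patient_ids=None) -> "ProbabilityOfCorrectClass":
        from .catalog import DEFAULT_CATALOG, FeatureSpec
        from .cohort import Cohort as _Cohort

        df = X.copy()
        df.insert(0, "patient_id", [f"P{i:05d}" for i in range(len(X))] if patient_ids is None else list(patient_ids))
        if "age" not in df.columns:
            df["age"] = 65.0
        if "sex" not in df.columns:
            df["sex"] = "F"
        df["diagnosis"] = np.asarray(y, dtype=object)
        known = {s.name: s for s in DEFAULT_CATALOG}
        catalog = tuple(
            known.get(c, FeatureSpec(c, "NP")) for c in X.columns
        )
        cohort = _Cohort(data=df.reset_index(drop=True), catalog=catalog, corrected=True)
        self.model_ = build_pcc_model(
            cohort, feature_subset=self.feature_subset, k=self.k, min_ref=self.min_ref
        )
        self.dsi_ = DiseaseStateIndexClassifier(
            feature_subset=self.feature_subset, min_ref=self.min_ref
        ).fit(X, np.asarray(y, dtype=object))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        res = self.dsi_.evaluate(X)
        values, _ = estimate_pcc_batch(
            self.model_, res["d1"].to_numpy(), res["margin"].to_numpy()
        )
        return values


# -- serialization ---------------------------------------------------------


def pcc_model_to_json(model: PCCModel, path) -> None:
    doc = {
        "d1": model.d1.tolist(),
        "delta": model.delta.tolist(),
        "correct": model.correct.astype(int).tolist(),
        "k": model.k,
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "feature_subset": list(model.feature_subset),
        "patient_ids": list(model.patient_ids),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def pcc_model_from_json(path) -> PCCModel:
    with open(path) as fh:
        doc = json.load(fh)
    return PCCModel(
        d1=np.asarray(doc["d1"], dtype=float),
        delta=np.asarray(doc["delta"], dtype=float),
        correct=np.asarray(doc["correct"], dtype=bool),
        k=int(doc["k"]),
        mean=np.asarray(doc["mean"], dtype=float),
        sd=np.asarray(doc["sd"], dtype=float),
        feature_subset=tuple(doc["feature_subset"]),
        patient_ids=tuple(doc["patient_ids"]),
    )
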