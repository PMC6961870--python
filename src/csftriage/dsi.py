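"""Disease State Index (DSI) classifier.

The DSI is a nonparametric, supervised similarity score in [0, 1] between a
patient's multimodal data and each diagnostic group (CONTROL, AD, FTD, VAD).
For every feature and every pairwise group comparison, a reference cohort
defines

* a *fitness function* ``f(x) = FN(x) / (FN(x) + FP(x))``, where FN and FP
  are the false-negative and false-positive rates obtained when the
  patient's own value ``x`` is used as the classification cutoff between
  the two groups, and
* a *relevance* weight, ``max_cutoff (sensitivity + specificity - 1)``
  (the Youden index), measuring how well the feature separates the pair.

The pairwise DSI is the relevance-weighted mean of fitness values over the
features observed for the patient — missing data simply drop out of the
average, so no imputation is ever needed. The total DSI for a group is the
unweighted mean of its three pairwise comparisons, and the predicted class
is the argmax. The margin ``d1 - d2`` between the two highest totals feeds
the confidence estimate (see :mod:`csftriage.pcc`).

Conventions fixed here (the published description leaves them open):
orientation of each fitness function is chosen per feature and pair to
maximize the Youden index, ties toward "higher value ⇒ positive group";
``f`` is evaluated from the empirical step counts directly (FN strict
``<``, FP ``≥``), with linear interpolation across intervals where
``FN + FP = 0``; reversed pairs are derived by complement (``1 - value``);
features with zero relevance carry zero weight, and a pair with only
zero-relevance evidence scores a neutral 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .catalog import CANONICAL_PAIRS, GROUPS
from .cohort import Cohort

DEFAULT_MIN_REF = 5

GroupPair = tuple[str, str]  # (positive_group, negative_group)


def _max_youden(pos_sorted: np.ndarray, neg_sorted: np.ndarray) -> float:
    """Maximum of sensitivity+specificity-1 over cutoffs, rule '>= c => positive'.

    Candidate cutoffs are the midpoints between consecutive distinct pooled
    values; the infinite cutoffs contribute J = 0.
    """
    pooled = np.unique(np.concatenate([pos_sorted, neg_sorted]))
    if pooled.size < 2:
        return 0.0
    cuts = (pooled[:-1] + pooled[1:]) / 2.0
    sens = 1.0 - np.searchsorted(pos_sorted, cuts, side="left") / pos_sorted.size
    spec = np.searchsorted(neg_sorted, cuts, side="left") / neg_sorted.size
    return float(max(0.0, np.max(sens + spec - 1.0)))


@dataclass
class FitnessFunction:
    """Empirical fitness function for one (feature, group pair).

    Stores the reference values transformed so that the positive group tends
    to higher values (``orientation`` is +1 for higher-is-positive, -1 for
    lower-is-positive; the transform is multiplication by the orientation).
    """

    orientation: int
    pos_ref: np.ndarray  # sorted, transformed positive-group reference values
    neg_ref: np.ndarray
    degenerate: bool = False
    feature: str | None = None
    pair: GroupPair | None = None

    def __call__(self, x):
        scalar = np.isscalar(x)
        t = self.orientation * np.asarray(x, dtype=float)
        t = np.atleast_1d(t)
        if self.degenerate:
            f = np.full(t.shape, 0.5)
        else:
            fn = np.searchsorted(self.pos_ref, t, side="left") / self.pos_ref.size
            fp = 1.0 - np.searchsorted(self.neg_ref, t, side="left") / self.neg_ref.size
            denom = fn + fp
            safe = np.where(denom > 0, denom, 1.0)
            f = np.where(denom > 0, fn / safe, 0.0)
            lo, hi = self.neg_ref[-1], self.pos_ref[0]
            if lo < hi:  # perfect separation: interpolate across the FN+FP=0 gap
                gap = (t > lo) & (t <= hi)
                f[gap] = (t[gap] - lo) / (hi - lo)
        return float(f[0]) if scalar else f

    @property
    def breakpoints(self) -> np.ndarray:
        """Sorted distinct pooled reference values on the original scale."""
        pooled = np.unique(np.concatenate([self.pos_ref, self.neg_ref]))
        return np.sort(self.orientation * pooled)

    def values_at_breakpoints(self) -> np.ndarray:
        return np.asarray(self(self.breakpoints))


def fit_fitness_function(pos_values, neg_values, *, feature=None, pair=None) -> FitnessFunction:
    """Fit the fitness function for one feature and group pair.

    Orientation is chosen to maximize the Youden index (ties toward
    higher-is-positive). If every reference value is identical across both
    groups, the function is degenerate (``f ≡ 0.5``) and flagged with a
    warning.
    """
    pos = np.sort(np.asarray(pos_values, dtype=float))
    neg = np.sort(np.asarray(neg_values, dtype=float))
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty reference group for fitness function")
    if pos[0] == pos[-1] == neg[0] == neg[-1]:
        warnings.warn(
            f"degenerate fitness function (all reference values identical)"
            + (f" for feature {feature}" if feature else ""),
            stacklevel=2,
        )
        return FitnessFunction(1, pos, neg, degenerate=True, feature=feature, pair=pair)
    j_high = _max_youden(pos, neg)
    # lower-is-positive: negate values so the positive group tends higher
    j_low = _max_youden(np.sort(-pos), np.sort(-neg))
    # ties (within rounding noise) break toward higher-is-positive
    if j_high >= j_low - 1e-12:
        return FitnessFunction(1, pos, neg, feature=feature, pair=pair)
    return FitnessFunction(-1, np.sort(-pos), np.sort(-neg), feature=feature, pair=pair)


def compute_relevance(pos_values, neg_values) -> float:
    """Discriminative weight of a feature for a pair: the maximal Youden
    index over cutoffs, under the better of the two orientations."""
    pos = np.sort(np.asarray(pos_values, dtype=float))
    neg = np.sort(np.asarray(neg_values, dtype=float))
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty reference group for relevance")
    return max(_max_youden(pos, neg), _max_youden(np.sort(-pos), np.sort(-neg)))


@dataclass
class PairFeatureFit:
    fitness: FitnessFunction
    relevance: float


@dataclass
class DSIResult:
    """Classification of one patient: per-group totals, pairwise values,
    the predicted group and the (d1, margin) coordinates used by PCC."""

    patient_id: str
    totals: dict[str, float]
    pairwise: dict[GroupPair, float]
    predicted: str
    d1: float
    d2: float
    margin: float
    n_features_used: int
    tie: bool = False


class DiseaseStateIndexClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class Disease State Index classifier.

    Parameters
    ----------
    feature_subset : iterable of str, optional
        Feature columns to use; defaults to every column of the training
        frame. The pre-CSF model uses neuropsychology + MRI + APOE, the
        full model adds the CSF analytes.
    min_ref : int, default 5
        Minimum observed reference values per group required for a feature
        to enter a pairwise comparison (and for each group overall).

    Attributes
    ----------
    classes_ : ndarray of str
        The four diagnostic groups present in ``y``.
    feature_names_ : tuple of str
        Features actually available in the training frame, in column order.
    pair_models_ : dict[(str, str), dict[str, PairFeatureFit]]
        Fitted fitness function and relevance per canonical pair per feature.
    group_sizes_ : dict[str, int]
    """

    def __init__(self, feature_subset=None, min_ref: int = DEFAULT_MIN_REF):
        self.feature_subset = feature_subset
        self.min_ref = min_ref

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "DiseaseStateIndexClassifier":
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        sizes = {g: int((y == g).sum()) for g in GROUPS}
        for g, n in sizes.items():
            if n == 0:
                raise ValueError(f"diagnostic group {g} is missing from the reference")
            if n < self.min_ref:
                raise ValueError(
                    f"diagnostic group {g} has {n} members (< min_ref={self.min_ref})"
                )
        subset = (
            tuple(c for c in X.columns if c in set(self.feature_subset))
            if self.feature_subset is not None
            else tuple(X.columns)
        )
        if not subset:
            raise ValueError("empty feature subset")
        cols = {f: X[f].to_numpy(dtype=float) for f in subset}
        group_idx = {g: np.flatnonzero(y == g) for g in GROUPS}
        pair_models: dict[GroupPair, dict[str, PairFeatureFit]] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-feature warnings
            for pair in CANONICAL_PAIRS:
                pos_g, neg_g = pair
                fits: dict[str, PairFeatureFit] = {}
                for f in subset:
                    pv = cols[f][group_idx[pos_g]]
                    nv = cols[f][group_idx[neg_g]]
                    pv, nv = pv[~np.isnan(pv)], nv[~np.isnan(nv)]
                    if pv.size < self.min_ref or nv.size < self.min_ref:
                        continue
                    fits[f] = _fit_pair_feature(pv, nv, feature=f, pair=pair)
                pair_models[pair] = fits
        self.classes_ = np.unique(y)
        self.feature_names_ = subset
        self.pair_models_ = pair_models
        self.group_sizes_ = sizes
        return self

    # -- evaluation --------------------------------------------------------

    def pairwise_values(self, X: pd.DataFrame) -> dict[GroupPair, np.ndarray]:
        """Pairwise DSI per canonical pair for every row (NaN = undefined:
        no observed feature available for that pair)."""
        self._check_fitted()
        n = len(X)
        out: dict[GroupPair, np.ndarray] = {}
        for pair, fits in self.pair_models_.items():
            num = np.zeros(n)
            den = np.zeros(n)
            cnt = np.zeros(n, dtype=int)
            for f, pf in fits.items():
                if f not in X.columns:
                    continue
                x = X[f].to_numpy(dtype=float)
                obs = ~np.isnan(x)
                if not obs.any():
                    continue
                cnt[obs] += 1
                if pf.relevance > 0:
                    num[obs] += pf.relevance * pf.fitness(x[obs])
                    den[obs] += pf.relevance
            vals = np.full(n, np.nan)
            weighted = den > 0
            vals[weighted] = num[weighted] / den[weighted]
            vals[(~weighted) & (cnt > 0)] = 0.5  # only zero-relevance evidence
            out[pair] = vals
        return out

    def evaluate(self, X: pd.DataFrame, patient_ids=None) -> pd.DataFrame:
        """Full per-patient classification table.

        Returns a DataFrame with one row per input row: total DSI per group
        (``dsi_CONTROL`` ...), ``predicted``, ``d1``, ``d2``, ``margin``,
        ``n_features_used`` and ``tie``.
        """
        pw = self.pairwise_values(X)
        totals = self._totals_from_pairwise(pw, len(X))
        mat = np.column_stack([totals[g] for g in GROUPS])
        if np.isnan(mat).all(axis=1).any():
            bad = int(np.flatnonzero(np.isnan(mat).all(axis=1))[0])
            raise ValueError(
                f"no pairwise DSI defined for any group (row {bad}); "
                f"usable features: {sorted(self.feature_names_)}"
            )
        # a group with no defined pairwise comparison cannot be predicted
        order = np.where(np.isnan(mat), -np.inf, mat)
        best = np.argmax(order, axis=1)  # first max wins: CONTROL<AD<FTD<VAD
        d_sorted = np.sort(np.where(np.isnan(mat), -np.inf, mat), axis=1)[:, ::-1]
        d1 = d_sorted[:, 0]
        d2 = np.where(np.isfinite(d_sorted[:, 1]), d_sorted[:, 1], 0.0)
        tie = (order == d1[:, None]).sum(axis=1) > 1
        n_used = np.zeros(len(X), dtype=int)
        for f in self.feature_names_:
            if f in X.columns:
                n_used += (~X[f].isna()).to_numpy()
        out = pd.DataFrame(
            {f"dsi_{g}": totals[g] for g in GROUPS},
            index=X.index,
        )
        out["predicted"] = np.asarray(GROUPS, dtype=object)[best]
        out["d1"] = d1
        out["d2"] = d2
        out["margin"] = d1 - d2
        out["n_features_used"] = n_used
        out["tie"] = tie
        if patient_ids is not None:
            out.insert(0, "patient_id", np.asarray(patient_ids, dtype=object))
        return out

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Total DSI per group, columns ordered CONTROL, AD, FTD, VAD."""
        pw = self.pairwise_values(X)
        totals = self._totals_from_pairwise(pw, len(X))
        return np.column_stack([totals[g] for g in GROUPS])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.evaluate(X)["predicted"].to_numpy()

    def _totals_from_pairwise(
        self, pw: dict[GroupPair, np.ndarray], n: int
    ) -> dict[str, np.ndarray]:
        totals: dict[str, np.ndarray] = {}
        for g in GROUPS:
            vals = []
            for other in GROUPS:
                if other == g:
                    continue
                if (g, other) in pw:
                    vals.append(pw[(g, other)])
                else:  # reversed pair: complement of the stored value
                    vals.append(1.0 - pw[(other, g)])
            stack = np.column_stack(vals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                totals[g] = np.nanmean(stack, axis=1)
        return totals

    def _check_fitted(self) -> None:
        if not hasattr(self, "pair_models_"):
            raise ValueError("classifier is not fitted")

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        self._check_fitted()
        doc = {
            "feature_subset": list(self.feature_names_),
            "min_ref": self.min_ref,
            "group_sizes": self.group_sizes_,
            "pairs": [
                {
                    "positive": pair[0],
                    "negative": pair[1],
                    "features": {
                        f: {
                            "orientation": pf.fitness.orientation,
                            "pos_ref": (pf.fitness.orientation * pf.fitness.pos_ref).tolist(),
                            "neg_ref": (pf.fitness.orientation * pf.fitness.neg_ref).tolist(),
                            "degenerate": pf.fitness.degenerate,
                            "relevance": pf.relevance,
                            "breakpoints": pf.fitness.breakpoints.tolist(),
                            "fitness_values": pf.fitness.values_at_breakpoints().tolist(),
                        }
                        for f, pf in self.pair_models_[pair].items()
                    },
                }
                for pair in CANONICAL_PAIRS
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "DiseaseStateIndexClassifier":
        with open(path) as fh:
            doc = json.load(fh)
        clf = cls(feature_subset=doc["feature_subset"], min_ref=doc["min_ref"])
        clf.feature_names_ = tuple(doc["feature_subset"])
        clf.group_sizes_ = doc["group_sizes"]
        clf.classes_ = np.unique(np.asarray(GROUPS, dtype=object))
        pair_models: dict[GroupPair, dict[str, PairFeatureFit]] = {}
        for entry in doc["pairs"]:
            pair = (entry["positive"], entry["negative"])
            fits = {}
            for f, d in entry["features"].items():
                ori = int(d["orientation"])
                fn = FitnessFunction(
                    ori,
                    np.sort(ori * np.asarray(d["pos_ref"], dtype=float)),
                    np.sort(ori * np.asarray(d["neg_ref"], dtype=float)),
                    degenerate=bool(d["degenerate"]),
                    feature=f,
                    pair=pair,
                )
                fits[f] = PairFeatureFit(fn, float(d["relevance"]))
            pair_models[pair] = fits
        clf.pair_models_ = pair_models
        return clf


def _fit_pair_feature(pos: np.ndarray, neg: np.ndarray, *, feature=None, pair=None) -> PairFeatureFit:
    """Fit fitness + relevance for one (pair, feature) in a single pass."""
    fitness = fit_fitness_function(pos, neg, feature=feature, pair=pair)
    relevance = max(
        _max_youden(np.sort(pos), np.sort(neg)),
        _max_youden(np.sort(-pos), np.sort(-neg)),
    )
    return PairFeatureFit(fitness, relevance)


# -- cohort-level functional wrappers -------------------------------------


def fit_dsi_model(
    reference: Cohort, feature_subset=None, min_ref: int = DEFAULT_MIN_REF
) -> DiseaseStateIndexClassifier:
    """Fit the DSI classifier on a corrected, labeled reference cohort."""
    if not reference.corrected:
        raise ValueError("reference cohort must be covariate-corrected first")
    y = reference.data["diagnosis"]
    if y.isna().any():
        raise ValueError("reference cohort must be fully labeled")
    X = reference.data[list(reference.feature_names)]
    return DiseaseStateIndexClassifier(
        feature_subset=feature_subset, min_ref=min_ref
    ).fit(X, y.to_numpy(dtype=object))


def pairwise_dsi(
    model: DiseaseStateIndexClassifier, record: pd.Series, pair: GroupPair
) -> float:
    """Pairwise DSI of one record for an ordered pair (NaN = undefined).

    Reversed (non-canonical) pairs are derived by complement.
    """
    frame = record.to_frame().T
    cols = [f for f in model.feature_names_ if f in frame.columns]
    frame = frame[cols].astype(float)
    pw = model.pairwise_values(frame)
    if pair in pw:
        return float(pw[pair][0])
    rev = (pair[1], pair[0])
    if rev in pw:
        return float(1.0 - pw[rev][0])
    raise ValueError(f"unknown group pair {pair}")


def total_dsi(model: DiseaseStateIndexClassifier, record: pd.Series) -> DSIResult:
    """Total DSI per group and predicted class for one record."""
    frame = record.to_frame().T
    cols = [f for f in model.feature_names_ if f in frame.columns]
    res = model.evaluate(frame[cols].astype(float)).iloc[0]
    pw = {
        pair: float(v[0])
        for pair, v in model.pairwise_values(frame[cols].astype(float)).items()
    }
    return DSIResult(
        patient_id=str(record.get("patient_id", "")),
        totals={g: float(res[f"dsi_{g}"]) for g in GROUPS},
        pairwise=pw,
        predicted=str(res["predicted"]),
        d1=float(res["d1"]),
        d2=float(res["d2"]),
        margin=float(res["margin"]),
        n_features_used=int(res["n_features_used"]),
        tie=bool(res["tie"]),
    )
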