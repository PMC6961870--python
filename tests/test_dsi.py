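"""Disease State Index: fitness functions, relevance, pairwise/total DSI."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csftriage import (
    CANONICAL_PAIRS,
    GROUPS,
    DiseaseStateIndexClassifier,
    compute_relevance,
    fit_fitness_function,
    pairwise_dsi,
    total_dsi,
)
from csftriage.dsi import PairFeatureFit, _fit_pair_feature

from oracles import (
    fitness_oracle,
    orientation_oracle,
    pairwise_dsi_oracle,
    relevance_oracle,
    total_dsi_oracle,
)


# -- fitness function ------------------------------------------------------


@pytest.mark.parametrize(
    "pos, neg, x, expected",
    [
        ([1, 3, 5], [0, 2, 4], 2.5, 0.5),  # FN=1/3, FP=1/3
        ([1, 3, 5], [0, 2, 4], -1.0, 0.0),  # below pooled minimum
        ([1, 3, 5], [0, 2, 4], 6.0, 1.0),  # above pooled maximum
        ([10, 11], [0, 1], 5.5, 0.5),  # midpoint of the FN+FP=0 gap
    ],
)
def test_fitness_matches_hand_computed_rates(pos, neg, x, expected):
    f = fit_fitness_function(pos, neg)
    assert f(x) == pytest.approx(expected, abs=1e-12)


def test_degenerate_reference_yields_neutral_fitness():
    with pytest.warns(UserWarning, match="degenerate"):
        f = fit_fitness_function([4.0, 4.0], [4.0, 4.0, 4.0])
    assert f.degenerate
    assert f(3.0) == 0.5 and f(4.0) == 0.5 and f(5.0) == 0.5


def test_empty_reference_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        fit_fitness_function([], [1.0])


@pytest.mark.parametrize(
    "pos, neg, expected",
    [
        ([1, 3, 5], [0, 2, 4], 1 / 3),
        ([2, 3], [0, 1], 1.0),  # perfectly separated
        ([1, 2, 3], [1, 2, 3], 0.0),  # identical multisets
    ],
)
def test_relevance_matches_exhaustive_scan(pos, neg, expected):
    assert compute_relevance(pos, neg) == pytest.approx(expected, abs=1e-12)


def test_fitness_and_relevance_match_brute_force_oracle(rng):
    """Random small references: direct-counting and exhaustive-scan oracles
    agree with the vectorized implementation to 1e-9."""
    for _ in range(200):
        n_pos = rng.integers(1, 9)
        n_neg = rng.integers(1, 9)
        # mix of continuous values and ties
        pool = np.round(rng.normal(0, 2, size=20), 1)
        pos = list(rng.choice(pool, size=n_pos))
        neg = list(rng.choice(pool, size=n_neg))
        if min(pos) == max(pos) == min(neg) == max(neg):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit_fitness_function(pos, neg)
            rel = compute_relevance(pos, neg)
        assert rel == pytest.approx(relevance_oracle(pos, neg), abs=1e-9)
        assert f.orientation == orientation_oracle(pos, neg)
        for x in np.concatenate([pool, pool + 0.05, [-100, 100]]):
            assert f(float(x)) == pytest.approx(
                fitness_oracle(pos, neg, f.orientation, float(x)), abs=1e-9
            )


@given(
    pos=st.lists(st.floats(-50, 50), min_size=1, max_size=12),
    neg=st.lists(st.floats(-50, 50), min_size=1, max_size=12),
)
@settings(max_examples=150, deadline=None)
def test_fitness_is_bounded_and_monotone(pos, neg):
    if min(pos) == max(pos) == min(neg) == max(neg):
        return
    f = fit_fitness_function(pos, neg)
    grid = np.linspace(min(pos + neg) - 1, max(pos + neg) + 1, 101)
    vals = np.asarray(f(f.orientation * grid))  # along the orientation axis
    assert (vals >= -1e-12).all() and (vals <= 1 + 1e-12).all()
    assert (np.diff(vals) >= -1e-12).all()


# -- weighting and totals --------------------------------------------------


def test_pairwise_dsi_is_relevance_weighted_mean():
    """Two features with relevances 0.5 and 0.25 and fitness values 1 and 0
    combine to (0.5*1 + 0.25*0) / 0.75 = 2/3."""
    clf = DiseaseStateIndexClassifier()
    fits = {
        "a": _fit_pair_feature(np.array([1.0, 2.0]), np.array([0.0, 1.0])),
        "b": _fit_pair_feature(
            np.array([0.0, 1.0, 2.0, 3.0]), np.array([-1.0, 0.0, 1.0, 2.0])
        ),
    }
    assert fits["a"].relevance == pytest.approx(0.5)
    assert fits["b"].relevance == pytest.approx(0.25)
    clf.pair_models_ = {("AD", "CONTROL"): fits}
    clf.feature_names_ = ("a", "b")
    clf.group_sizes_ = {}
    X = pd.DataFrame({"a": [3.0], "b": [-5.0]})  # fitness 1.0 and 0.0
    vals = clf.pairwise_values(X)[("AD", "CONTROL")]
    assert vals[0] == pytest.approx(2 / 3, abs=1e-12)


def _reference_frame(rng, n_per_group=8, features=("f1", "f2"), missing=0.0):
    rows = []
    for gi, g in enumerate(GROUPS):
        for i in range(n_per_group):
            row = {"diagnosis": g}
            for fj, f in enumerate(features):
                v = rng.normal(gi * 1.5 + fj, 1.0)
                row[f] = np.nan if rng.uniform() < missing else v
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[list(features)], df["diagnosis"].to_numpy(dtype=object)


def test_totals_match_brute_force_oracle_on_small_reference(rng):
    """8 cases per group, 2 features: totals, prediction and margin equal an
    independent reimplementation built on raw counting."""
    X, y = _reference_frame(rng, missing=0.15)
    clf = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
    ref_values = {
        f: {g: [v for v in X[f][y == g] if not np.isnan(v)] for g in GROUPS}
        for f in X.columns
    }
    queries = pd.DataFrame(
        {"f1": rng.normal(2, 2, size=12), "f2": rng.normal(2, 2, size=12)}
    )
    res = clf.evaluate(queries)
    for i in range(len(queries)):
        record = {f: float(queries[f].iloc[i]) for f in queries.columns}
        totals, predicted, d1, margin = total_dsi_oracle(ref_values, record)
        for g in GROUPS:
            assert res[f"dsi_{g}"].iloc[i] == pytest.approx(totals[g], abs=1e-9)
        assert res["predicted"].iloc[i] == predicted
        assert res["d1"].iloc[i] == pytest.approx(d1, abs=1e-9)
        assert res["margin"].iloc[i] == pytest.approx(margin, abs=1e-9)
        for pair in CANONICAL_PAIRS:
            got = clf.pairwise_values(queries.iloc[[i]])[pair][0]
            want = pairwise_dsi_oracle(ref_values, record, pair)
            assert got == pytest.approx(want, abs=1e-9)


def test_complement_symmetry_for_fully_observed_records(rng):
    X, y = _reference_frame(rng)
    clf = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
    queries = pd.DataFrame({"f1": rng.normal(2, 3, 9), "f2": rng.normal(2, 3, 9)})
    for pair in CANONICAL_PAIRS:
        fwd = [pairwise_dsi(clf, queries.iloc[i], pair) for i in range(9)]
        rev = [pairwise_dsi(clf, queries.iloc[i], pair[::-1]) for i in range(9)]
        np.testing.assert_allclose(np.array(fwd) + np.array(rev), 1.0, atol=1e-9)


def test_missing_feature_equals_feature_excluded_from_subset(rng):
    X, y = _reference_frame(rng, features=("f1", "f2", "f3"))
    clf_full = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
    clf_wo = DiseaseStateIndexClassifier(
        feature_subset={"f1", "f2"}, min_ref=5
    ).fit(X, y)
    q = pd.DataFrame({"f1": [1.2], "f2": [0.4], "f3": [np.nan]})
    res_full = clf_full.evaluate(q)
    res_wo = clf_wo.evaluate(q[["f1", "f2"]])
    for g in GROUPS:
        assert res_full[f"dsi_{g}"].iloc[0] == pytest.approx(
            res_wo[f"dsi_{g}"].iloc[0], abs=1e-12
        )


def test_all_degenerate_features_tie_resolves_to_first_group():
    X = pd.DataFrame({"f1": [1.0] * 24})
    y = np.repeat(GROUPS, 6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
        res = clf.evaluate(pd.DataFrame({"f1": [1.0]}))
    for g in GROUPS:
        assert res[f"dsi_{g}"].iloc[0] == pytest.approx(0.5)
    assert res["predicted"].iloc[0] == "CONTROL"
    assert bool(res["tie"].iloc[0])


def test_missing_group_is_rejected_by_name():
    X = pd.DataFrame({"f1": np.arange(18.0)})
    y = np.repeat(["CONTROL", "AD", "FTD"], 6)
    with pytest.raises(ValueError, match="VAD"):
        DiseaseStateIndexClassifier(min_ref=5).fit(X, y)


def test_total_dsi_arithmetic_and_record_wrapper(rng):
    X, y = _reference_frame(rng)
    clf = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
    record = pd.Series({"patient_id": "Q1", "f1": 2.0, "f2": 1.0})
    result = total_dsi(clf, record)
    expected = {
        g: np.mean(
            [
                result.pairwise[(g, o)]
                if (g, o) in result.pairwise
                else 1 - result.pairwise[(o, g)]
                for o in GROUPS
                if o != g
            ]
        )
        for g in GROUPS
    }
    for g in GROUPS:
        assert result.totals[g] == pytest.approx(expected[g], abs=1e-12)
    assert result.predicted == max(GROUPS, key=lambda g: result.totals[g])
    assert result.margin == pytest.approx(result.d1 - result.d2)


def test_refit_is_deterministic_and_json_round_trips(tmp_path, rng):
    X, y = _reference_frame(rng)
    clf1 = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
    clf2 = DiseaseStateIndexClassifier(min_ref=5).fit(X, y)
    q = pd.DataFrame({"f1": rng.normal(2, 2, 7), "f2": rng.normal(2, 2, 7)})
    pd.testing.assert_frame_equal(clf1.evaluate(q), clf2.evaluate(q))
    path = tmp_path / "model.json"
    clf1.to_json(path)
    clf3 = DiseaseStateIndexClassifier.from_json(path)
    pd.testing.assert_frame_equal(clf1.evaluate(q), clf3.evaluate(q))


def test_separation_scale_never_decreases_median_margin():
    from csftriage import AgeSexCorrector, fit_dsi_model, generate_cohort, scaled_config

    for seed in range(5):
        medians = []
        for scale in (0.5, 1.0, 2.0):
            cfg = scaled_config(240, seed=seed, separation_scale=scale)
            raw = generate_cohort(cfg)
            cohort = AgeSexCorrector().fit(raw).transform(raw)
            clf = fit_dsi_model(cohort)
            res = clf.evaluate(cohort.data[list(cohort.feature_names)])
            medians.append(float(res["margin"].median()))
        assert medians[0] <= medians[1] + 1e-9
        assert medians[1] <= medians[2] + 1e-9
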