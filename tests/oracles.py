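"""Independent brute-force oracles used by the test suite.

Everything here is written with plain loops and direct counting, on
purpose: these implementations share no code path with the package and
serve as the ground truth for fitness functions, relevance weights, DSI
averaging and the stepwise scenario logic on small references.
"""

from __future__ import annotations

import math

from csftriage.catalog import CANONICAL_PAIRS, GROUPS


def fitness_oracle(pos: list[float], neg: list[float], orientation: int, x: float) -> float:
    """f(x) = FN/(FN+FP) by direct counting; linear interpolation across
    the FN+FP = 0 gap. ``orientation`` +1 means higher-is-positive."""
    pos_t = sorted(orientation * v for v in pos)
    neg_t = sorted(orientation * v for v in neg)
    t = orientation * x
    fn = sum(1 for v in pos_t if v < t) / len(pos_t)
    fp = sum(1 for v in neg_t if v >= t) / len(neg_t)
    if fn + fp > 0:
        return fn / (fn + fp)
    lo, hi = max(neg_t), min(pos_t)  # perfect-separation gap
    return (t - lo) / (hi - lo)


def youden_oracle(pos: list[float], neg: list[float], orientation: int) -> float:
    """Exhaustive cutoff scan of sensitivity+specificity-1 for the rule
    'transformed value >= cutoff => positive'."""
    pos_t = [orientation * v for v in pos]
    neg_t = [orientation * v for v in neg]
    pooled = sorted(set(pos_t + neg_t))
    cuts = [-math.inf, math.inf]
    for a, b in zip(pooled, pooled[1:]):
        cuts.append((a + b) / 2)
    cuts.extend(pooled)  # cutoffs at the values themselves
    best = 0.0
    for c in cuts:
        sens = sum(1 for v in pos_t if v >= c) / len(pos_t)
        spec = sum(1 for v in neg_t if v < c) / len(neg_t)
        best = max(best, sens + spec - 1)
    return best


def relevance_oracle(pos: list[float], neg: list[float]) -> float:
    return max(youden_oracle(pos, neg, 1), youden_oracle(pos, neg, -1))


def orientation_oracle(pos: list[float], neg: list[float]) -> int:
    """+1 if higher-is-positive wins (ties toward +1), else -1."""
    return 1 if youden_oracle(pos, neg, 1) >= youden_oracle(pos, neg, -1) else -1


def pairwise_dsi_oracle(
    ref_values: dict[str, dict[str, list[float]]],
    record: dict[str, float],
    pair: tuple[str, str],
    min_ref: int = 5,
) -> float:
    """Relevance-weighted mean of fitness values over observed features.

    ``ref_values[feature][group]`` holds the observed reference values.
    Returns NaN when no observed feature is usable for the pair.
    """
    pos_g, neg_g = pair
    num = den = 0.0
    n_obs = 0
    for feat, by_group in ref_values.items():
        x = record.get(feat)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            continue
        pos, neg = by_group[pos_g], by_group[neg_g]
        if len(pos) < min_ref or len(neg) < min_ref:
            continue
        n_obs += 1
        if all(v == pos[0] for v in pos + neg):
            continue  # degenerate: relevance 0
        w = relevance_oracle(pos, neg)
        if w == 0:
            continue
        ori = orientation_oracle(pos, neg)
        num += w * fitness_oracle(pos, neg, ori, x)
        den += w
    if n_obs == 0:
        return math.nan
    if den == 0:
        return 0.5
    return num / den


def total_dsi_oracle(
    ref_values: dict[str, dict[str, list[float]]],
    record: dict[str, float],
    min_ref: int = 5,
) -> tuple[dict[str, float], str, float, float]:
    """(totals, predicted, d1, margin) recomputed from raw counts.

    Canonical pairs are fitted directly; reversed pairs by complement.
    """
    pw = {
        pair: pairwise_dsi_oracle(ref_values, record, pair, min_ref)
        for pair in CANONICAL_PAIRS
    }
    totals = {}
    for g in GROUPS:
        vals = []
        for other in GROUPS:
            if other == g:
                continue
            if (g, other) in pw:
                v = pw[(g, other)]
            else:
                v = 1.0 - pw[(other, g)]
            if not math.isnan(v):
                vals.append(v)
        totals[g] = sum(vals) / len(vals) if vals else math.nan
    predicted = max(GROUPS, key=lambda g: (totals[g], -GROUPS.index(g)))
    ordered = sorted((v for v in totals.values() if not math.isnan(v)), reverse=True)
    d1 = ordered[0]
    d2 = ordered[1] if len(ordered) > 1 else 0.0
    return totals, predicted, d1, d1 - d2


def scenario_a_oracle(
    pcc_step1: float,
    pcc_sim_pos: float,
    pcc_sim_neg: float,
    pcc_actual: float,
    threshold: float,
) -> tuple[bool, str, int, bool]:
    """Straight-line transcription of the stepwise flow chart.

    Returns (csf_tested, trigger, decision_group, diagnosed).
    """
    if pcc_step1 >= threshold:
        return False, "n/a", 1, True
    pos_hit = pcc_sim_pos >= threshold
    neg_hit = pcc_sim_neg >= threshold
    if not pos_hit and not neg_hit:
        return False, "none", 2, False
    if pos_hit and neg_hit:
        trigger = "both"
    elif pos_hit:
        trigger = "positive_only"
    else:
        trigger = "negative_only"
    if pcc_actual >= threshold:
        return True, trigger, 3, True
    return True, trigger, 4, False


def proportion_diff_oracle(x1: int, n1: int, x2: int, n2: int) -> float:
    """Percentage-point difference between two printed counts."""
    return 100.0 * (x1 / n1 - x2 / n2)
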