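"""Statistics: printed-table conventions, enumeration oracles, invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pleurovol.stats import (
    classify_at_cutoffs,
    fisher_exact,
    logistic_cohort,
    logistic_multivariable,
    logistic_univariable,
    mann_whitney,
    median_iqr,
    roc_cutoff,
    screen_univariable,
    spearman,
    synthetic_cohort,
)

# ---------------------------------------------------------------------------
# median / IQR
# ---------------------------------------------------------------------------


def test_median_iqr_reproduces_published_r2_summaries(table2):
    assert median_iqr(table2["tlc_pct"]) == (75.0, 71.0, 80.0)
    assert median_iqr(table2["burden_mm"]) == (133.0, 70.0, 181.0)
    med, q1, q3 = median_iqr(table2["ipsilateral_volume_cm3"])
    assert (round(med), round(q1), round(q3)) == (1545, 1322, 1782)
    med, q1, q3 = median_iqr(table2["diff_pct"])
    assert (med, q1, q3) == (47.01, 28.39, 59.01)


def test_median_iqr_single_value_and_empty():
    assert median_iqr([7.0]) == (7.0, 7.0, 7.0)
    with pytest.raises(ValueError):
        median_iqr([])


@settings(deadline=None, max_examples=50)
@given(hst.lists(hst.floats(-1e6, 1e6), min_size=1, max_size=40), hst.randoms())
def test_median_iqr_ordered_and_permutation_invariant(xs, rnd):
    med, q1, q3 = median_iqr(xs)
    assert min(xs) <= q1 <= med <= q3 <= max(xs)
    shuffled = list(xs)
    rnd.shuffle(shuffled)
    assert median_iqr(shuffled) == (med, q1, q3)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def test_mann_whitney_identical_groups_p_one():
    with pytest.warns(UserWarning):
        _, p = mann_whitney([5, 5, 5], [5, 5])
    assert p == 1.0


def test_mann_whitney_fully_separated_small_groups_exact():
    # all 20 assignments of ranks: the two extreme tables give p = 2/20
    u, p = mann_whitney([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_mann_whitney_power_at_observed_tlc_gap():
    # shift alternative sized like the published TLC gap (89 vs 75, spread
    # from the IQRs), n = 43 vs 15: power > 0.8 at alpha = 0.05
    rng = np.random.default_rng(1)
    hits = 0
    reps = 2000
    for _ in range(reps):
        a = rng.normal(89, 13, 43)
        b = rng.normal(75, 13, 15)
        hits += mann_whitney(a, b)[1] < 0.05
    assert hits / reps > 0.8


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------


def _fisher_oracle_p(table):
    """Two-sided p by brute-force enumeration of all tables with the
    observed margins (hypergeometric null)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def test_fisher_on_published_sex_by_outcome_table():
    res = fisher_exact([[25, 18], [14, 1]])
    assert res.p_value < 0.05  # printed p = 0.01


def test_fisher_balanced_table_is_null():
    res = fisher_exact([[5, 5], [5, 5]])
    assert res.p_value == 1.0
    assert res.odds_ratio == pytest.approx(1.0)


def test_fisher_zero_margin_flagged():
    res = fisher_exact([[0, 0], [3, 4]])
    assert not res.or_defined and res.p_value == 1.0


@pytest.mark.parametrize(
    "table",
    [
        [[2, 3], [4, 1]],
        [[25, 18], [14, 1]],
        [[1, 7], [6, 2]],
        [[0, 5], [5, 0]],
        [[3, 3], [3, 3]],
    ],
)
def test_fisher_p_matches_enumeration_oracle(table):
    assert fisher_exact(table).p_value == pytest.approx(_fisher_oracle_p(table))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_spearman_perfect_monotone():
    x = [1.0, 2.0, 5.0, 9.0]
    assert spearman(x, x)[0] == pytest.approx(1.0)
    assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)


def test_spearman_constant_input_flagged():
    with pytest.warns(UserWarning):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(rho)


def test_spearman_exact_p_matches_permutation_oracle():
    x = [10.0, 4.0, 7.0, 1.0, 9.0, 3.0]
    y = [8.0, 2.0, 5.0, 3.0, 9.0, 1.0]
    n = len(x)
    rx = [sorted(x).index(v) + 1 for v in x]
    ry = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    rho_oracle = 1 - 6 * d2 / (n * (n**2 - 1))

    def rho_of(perm):
        dd = sum((a - b) ** 2 for a, b in zip(rx, perm))
        return 1 - 6 * dd / (n * (n**2 - 1))

    perms = list(itertools.permutations(ry))
    p_oracle = sum(abs(rho_of(pm)) >= abs(rho_oracle) - 1e-12 for pm in perms) / len(perms)
    rho, p = spearman(x, y, method="exact")
    assert rho == pytest.approx(rho_oracle)
    assert p == pytest.approx(p_oracle)


# ---------------------------------------------------------------------------
# ROC and cut-offs
# ---------------------------------------------------------------------------


def test_roc_perfect_separation():
    res = roc_cutoff([1, 2, 3, 10, 11], [False, False, False, True, True])
    assert res.auc == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0


def test_roc_permuted_labels_have_null_auc():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=58)
    aucs = []
    for _ in range(200):
        lab = np.zeros(58, dtype=bool)
        lab[rng.choice(58, 15, replace=False)] = True
        aucs.append(roc_cutoff(vals, lab).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_roc_auc_equals_rank_sum_identity():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=30)
    lab = rng.random(30) < 0.4
    if lab.sum() in (0, 30):
        lab[0] = ~lab[0]
    res = roc_cutoff(vals, lab, direction="above")
    u, _ = mann_whitney(vals[lab], vals[~lab])
    assert res.auc == pytest.approx(u / (lab.sum() * (~lab).sum()))


def _roc_oracle(values, labels, direction):
    """Exhaustive search over every midpoint cut-off."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(values)
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2.0:
        pos = values > c if direction == "above" else values < c
        sens = (pos & labels).sum() / labels.sum()
        spec = (~pos & ~labels).sum() / (~labels).sum()
        key = (sens + spec, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    return best[1:]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("direction", ["above", "below"])
def test_roc_cutoff_matches_exhaustive_oracle(seed, direction):
    rng = np.random.default_rng(seed)
    vals = np.round(rng.normal(50, 10, 12), 1)
    lab = rng.random(12) < 0.4
    if lab.sum() in (0, 12):
        lab[0] = ~lab[0]
    res = roc_cutoff(vals, lab, direction=direction)
    cut, sens, spec = _roc_oracle(vals, lab, direction)
    assert res.cutoff == pytest.approx(cut)
    assert res.sensitivity == pytest.approx(sens)
    assert res.specificity == pytest.approx(spec)


def test_roc_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    vals = rng.normal(size=40)
    lab = rng.random(40) < 0.5
    if lab.sum() in (0, 40):
        lab[0] = ~lab[0]
    assert roc_cutoff(vals, lab).auc == pytest.approx(roc_auc_score(lab, vals))


def test_midpoint_convention_can_print_half_unit_cutoffs():
    # 77 | 78 around the class boundary -> printed TLC cut-off 77.5
    vals = np.array([70.0, 72.0, 75.0, 77.0, 78.0, 83.0, 89.0, 95.0])
    lab = np.array([True, True, True, True, False, False, False, False])
    res = roc_cutoff(vals, lab, direction="below")
    assert res.cutoff == 77.5


def test_constant_predictor_flagged():
    with pytest.warns(UserWarning):
        res = roc_cutoff([5, 5, 5, 5], [True, False, True, False])
    assert np.isnan(res.auc)


def test_classification_counts_on_published_cohort(table2):
    counts = classify_at_cutoffs(table2)
    assert counts == {"tlc_below": 11, "burden_above": 9, "both": 5, "n": 15}
    zero = table2.copy()
    zero["burden_mm"] = 0.0
    assert classify_at_cutoffs(zero)["burden_above"] == 0


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def test_logistic_separation_is_flagged_not_divergent():
    df = pd.DataFrame({"x": [0.0, 0, 0, 1, 1, 1],
                       "outcome": ["MCR"] * 3 + ["R2"] * 3})
    fit = logistic_univariable(df, "x")
    assert fit.separation


def test_logistic_recovers_known_coefficient_within_2_se():
    beta = 0.03
    df = logistic_cohort(500, {"burden_mm": (beta, 100.0, 40.0)}, intercept=-3.2, seed=5)
    fit = logistic_univariable(df, "burden_mm")
    eff = fit["burden_mm"]
    se = (np.log(eff.ci_high) - np.log(eff.odds_ratio)) / 1.959964
    assert not fit.separation
    assert abs(eff.coef - beta) < 2 * se


def test_logistic_null_ci_coverage():
    cover = 0
    reps = 500
    for s in range(reps):
        df = logistic_cohort(200, {"x": (0.0, 0.0, 1.0)}, intercept=0.0, seed=s)
        eff = logistic_univariable(df, "x")["x"]
        cover += eff.ci_low <= 1.0 <= eff.ci_high
    assert cover / reps >= 0.93


def test_univariable_screen_feeds_multivariable():
    df = logistic_cohort(
        400,
        {"signal": (1.0, 0.0, 1.0), "noise": (0.0, 0.0, 1.0)},
        intercept=-0.5,
        seed=9,
    )
    selected = screen_univariable(df, ["signal", "noise"])
    assert "signal" in selected
    fit = logistic_multivariable(df, selected)
    assert fit.scope == "multivariable"
    assert fit["signal"].odds_ratio > 1.5


def test_synthetic_cohort_marginals_are_plausible():
    df = synthetic_cohort(n_mcr=430, n_r2=150, seed=2)
    r2 = df[df.outcome == "R2"]
    mcr = df[df.outcome == "MCR"]
    assert median_iqr(r2["tlc_pct"])[0] == pytest.approx(75, rel=0.06)
    assert median_iqr(mcr["tlc_pct"])[0] == pytest.approx(89, rel=0.06)
    assert median_iqr(r2["burden_mm"])[0] > median_iqr(mcr["burden_mm"])[0]
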