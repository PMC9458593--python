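"""Agreement statistics: Bland–Altman, ICC, weighted kappa, subgroup tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sriaquant import (
    bland_altman,
    icc_consistency_average,
    icc_from_f,
    relevant_difference_flags,
    subgroup_difference,
    weighted_kappa,
)
from sriaquant.agreement import PairAgreement

# ------------------------------------------------------------ Bland–Altman


def test_constant_offset_pairs():
    pairs = [(p + 5.0, p) for p in (10.0, 20.0, 30.0, 40.0)]
    r = bland_altman(pairs)
    assert r.mean_diff == 5.0
    assert r.sd_diff == 0.0
    assert (r.loa_low, r.loa_high) == (5.0, 5.0)
    assert r.bias_slope_beta == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_bland_altman_matches_explicit_sums(seed):
    rng = np.random.default_rng(seed)
    f = rng.uniform(10, 60, 20)
    p = rng.uniform(10, 60, 20)
    r = bland_altman(np.column_stack([f, p]))

    d = [fi - pi for fi, pi in zip(f, p)]
    m = [(fi + pi) / 2 for fi, pi in zip(f, p)]
    n = len(d)
    mean = sum(d) / n
    sd = (sum((x - mean) ** 2 for x in d) / (n - 1)) ** 0.5
    mbar = sum(m) / n
    slope = sum((mi - mbar) * (di - mean) for mi, di in zip(m, d)) / sum(
        (mi - mbar) ** 2 for mi in m
    )
    assert r.mean_diff == pytest.approx(mean, rel=1e-12)
    assert r.sd_diff == pytest.approx(sd, rel=1e-12)
    assert r.loa_low == pytest.approx(mean - 1.96 * sd, rel=1e-12)
    assert r.loa_high == pytest.approx(mean + 1.96 * sd, rel=1e-12)
    assert r.bias_slope_beta == pytest.approx(slope, rel=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=3,
                max_size=30))
def test_limits_of_agreement_symmetry_invariant(pairs):
    r = bland_altman(pairs)
    assert r.loa_low + r.loa_high == pytest.approx(2 * r.mean_diff, abs=1e-9)
    assert r.loa_high - r.loa_low == pytest.approx(2 * 1.96 * r.sd_diff, abs=1e-9)


def test_too_few_pairs_and_degenerate_means():
    with pytest.raises(ValueError, match="at least 3"):
        bland_altman([(1.0, 2.0), (3.0, 4.0)])
    r = bland_altman([(12.0, 8.0), (11.0, 9.0), (14.0, 6.0)])  # all means 10
    assert not r.slope_defined
    assert np.isnan(r.bias_slope_beta)


def test_additive_only_artefact_slope_vanishes_at_large_n():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        p = rng.uniform(10, 60, 500)
        f = p + rng.normal(7.8, 3.0, 500)
        r = bland_altman(np.column_stack([f, p]))
        assert abs(r.bias_slope_beta) < 0.05


# ---------------------------------------------------------------- ICC


def test_icc_perfect_and_constant_shift_agreement():
    x = np.array([1.0, 4.0, 2.5, 7.0, 3.0, 9.0])
    assert icc_consistency_average(x, x).icc == pytest.approx(1.0)
    shifted = icc_consistency_average(x, x + 7.8)
    assert shifted.icc == pytest.approx(1.0)


def test_icc_identity_reproduces_published_summary():
    """An F of 3.212 on (72, 72) df corresponds to ICC 0.69 with the
    F-quantile interval (0.504, 0.805)."""
    r = icc_from_f(3.212, 72, 72)
    assert round(r.icc, 2) == 0.69
    assert r.ci_low == pytest.approx(0.504, abs=0.005)
    assert r.ci_high == pytest.approx(0.805, abs=0.005)
    assert r.ci_low <= r.icc <= r.ci_high


def test_icc_anova_path_equals_f_identity_path():
    rng = np.random.default_rng(3)
    subj = rng.uniform(10, 60, 40)
    x = subj + rng.normal(0, 4, 40)
    y = subj + rng.normal(0, 4, 40)
    r = icc_consistency_average(x, y)
    assert r.icc == pytest.approx(1.0 - 1.0 / r.f_value, rel=1e-12)
    identity = icc_from_f(r.f_value, r.df1, r.df2)
    assert r.icc == pytest.approx(identity.icc, rel=1e-12)
    assert r.ci_low == pytest.approx(identity.ci_low, rel=1e-12)


def test_icc_invariances_and_affine_rescaling():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 50, 25)
    y = x + rng.normal(0, 5, 25)
    base = icc_consistency_average(x, y).icc
    assert icc_consistency_average(x, y + 123.4).icc == pytest.approx(base, rel=1e-9)
    assert icc_consistency_average(3 * x + 2, 3 * y + 2).icc == pytest.approx(
        base, rel=1e-9
    )


def test_icc_cross_checked_against_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(21)
    subj = rng.uniform(10, 60, 30)
    x = subj + rng.normal(0, 5, 30)
    y = subj + rng.normal(0, 5, 30)
    ours = icc_consistency_average(x, y)
    long = pd.DataFrame({
        "subject": list(range(30)) * 2,
        "rater": ["a"] * 30 + ["b"] * 30,
        "score": np.concatenate([x, y]),
    })
    ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score").set_index("Type")
    assert ours.icc == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-6)
    assert ours.f_value == pytest.approx(ref.loc["ICC(C,k)", "F"], rel=1e-6)


def test_icc_degenerate_zero_error_flagged():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r = icc_consistency_average(x, x + 1.0)  # zero residual after rater shift
    assert r.degenerate and r.icc == 1.0


# ---------------------------------------------------------------- kappa


def test_kappa_extremes():
    assert weighted_kappa([0, 1, 2, 3], [0, 1, 2, 3]).kappa == pytest.approx(1.0)
    assert weighted_kappa([0, 3], [3, 0], n_categories=4).kappa == pytest.approx(-1.0)


def _kappa_brute_force(a, b, K):
    n = len(a)
    O = np.zeros((K, K))
    for i, j in zip(a, b):
        O[i, j] += 1 / n
    pa = O.sum(axis=1)
    pb = O.sum(axis=0)
    num = den = 0.0
    for i in range(K):
        for j in range(K):
            w = ((i - j) / (K - 1)) ** 2
            num += w * O[i, j]
            den += w * pa[i] * pb[j]
    return 1 - num / den


@pytest.mark.parametrize("seed", range(20))
def test_kappa_matches_confusion_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, 40)
    b = np.clip(a + rng.integers(-1, 2, 40), 0, 3)
    r = weighted_kappa(a, b, n_categories=4)
    assert r.kappa == pytest.approx(_kappa_brute_force(a, b, 4), rel=1e-12)
    assert r.confusion.sum() == 40


def test_kappa_cross_checked_against_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(33)
    a = rng.integers(0, 4, 60)
    b = rng.integers(0, 4, 60)
    ours = weighted_kappa(a, b, n_categories=4).kappa
    assert ours == pytest.approx(
        cohen_kappa_score(a, b, weights="quadratic"), abs=1e-10
    )


def test_two_category_quadratic_equals_unweighted():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 2, 50)
    b = rng.integers(0, 2, 50)
    quad = weighted_kappa(a, b, n_categories=2).kappa
    # unweighted kappa from the 2x2 table
    po = np.mean(a == b)
    pa1, pb1 = a.mean(), b.mean()
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    assert quad == pytest.approx((po - pe) / (1 - pe), rel=1e-12)


def test_kappa_single_category_undefined():
    r = weighted_kappa([1, 1, 1], [1, 1, 1], n_categories=4)
    assert not r.defined and np.isnan(r.kappa)


# ------------------------------------------------------------- subgroups


def test_identical_groups_give_central_u_and_p_near_one():
    r = subgroup_difference([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                            ["a", "a", "a", "b", "b", "b"])
    assert r.test_used == "mann_whitney"
    assert r.statistic == 3 * 3 / 2
    assert r.p > 0.9


def test_exact_mann_whitney_small_groups():
    r = subgroup_difference([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert r.test_used == "mann_whitney"
    assert r.p == pytest.approx(0.1, abs=1e-12)


def test_exact_mann_whitney_matches_enumeration_oracle():
    """Exact two-sided p equals brute-force enumeration of the U
    distribution over all group assignments."""
    rng = np.random.default_rng(17)
    for seed in range(20):
        rng = np.random.default_rng(seed)
        pooled = rng.normal(size=9)
        labels = ["a"] * 4 + ["b"] * 5
        g1 = pooled[:4]
        r = subgroup_difference(pooled, labels)

        def u_stat(idx_a):
            a = pooled[list(idx_a)]
            b = np.delete(pooled, list(idx_a))
            return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

        u_obs = u_stat(range(4))
        dist = [u_stat(c) for c in itertools.combinations(range(9), 4)]
        dist = np.asarray(dist)
        p_le = np.mean(dist <= u_obs)
        p_ge = np.mean(dist >= u_obs)
        p_exact = min(1.0, 2 * min(p_le, p_ge))
        assert r.p == pytest.approx(p_exact, abs=1e-12)


def test_normality_gate_selects_t_test_for_large_gaussian_groups():
    rng = np.random.default_rng(0)
    diffs = np.concatenate([rng.normal(5, 2, 30), rng.normal(9, 2, 30)])
    labels = ["a"] * 30 + ["b"] * 30
    r = subgroup_difference(diffs, labels)
    assert r.test_used == "t_test"
    assert r.p < 0.01


def test_skewed_groups_fall_back_to_mann_whitney():
    rng = np.random.default_rng(2)
    diffs = np.concatenate([rng.exponential(2, 30) ** 2,
                            rng.exponential(2, 30) ** 2 + 1])
    r = subgroup_difference(diffs, ["a"] * 30 + ["b"] * 30)
    assert r.test_used == "mann_whitney"


def test_factor_independent_artefact_is_not_flagged():
    """Under the null (artefact independent of the factor) the subgroup test
    should stay non-significant in >= 90% of replicates."""
    non_sig = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(7.8, 4.0, 40)
        labels = rng.random(40) < 0.5
        if labels.sum() < 3 or (~labels).sum() < 3:
            non_sig += 1
            continue
        if subgroup_difference(diffs, labels).p > 0.05:
            non_sig += 1
    assert non_sig >= 90


def test_subgroup_errors():
    with pytest.raises(ValueError, match="2 levels"):
        subgroup_difference([1.0, 2.0, 3.0], ["a", "a", "a"])
    with pytest.raises(ValueError, match="fewer than 3"):
        subgroup_difference([1, 2, 3, 4, 5], ["a"] * 4 + ["b"], factor="cit_gt20")


# ------------------------------------------------- relevant differences


@pytest.mark.parametrize(
    "frozen, paraffin, expected",
    [(41.0, 32.0, False), (45.0, 30.0, True), (50.0, 40.0, True)],
)
def test_sria_relevant_difference_threshold(frozen, paraffin, expected):
    assert relevant_difference_flags((frozen, paraffin)).sria_flag is expected


def test_score_flag_semantics():
    assert relevant_difference_flags((30, 30), 2, 2).score_flag is False
    assert relevant_difference_flags((30, 30), 2, 3).score_flag is True
    assert relevant_difference_flags((30, 30)).score_flag is None


# --------------------------------------------------------- PairAgreement


def test_pair_agreement_summary_reports_all_statistics():
    rng = np.random.default_rng(6)
    p = rng.uniform(15, 55, 30)
    f = p + rng.normal(7.8, 4, 30)
    grades = rng.integers(0, 4, 30)
    analysis = PairAgreement(list(zip(f, p)), grades_frozen=list(grades),
                             grades_paraffin=list(np.clip(grades + rng.integers(-1, 2, 30), 0, 3)))
    text = analysis.summary()
    assert "mean difference" in text and "ICC" in text and "kappa" in text
    flags = analysis.flags()
    assert len(flags) == 30
    assert (flags["difference_pp"] == f - p).all()
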