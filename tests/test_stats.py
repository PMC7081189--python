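"""Statistical battery: exact McNemar, variance tests, ICC, normality gate,
location dispatch, covariate screen, reclassification summaries."""

import numpy as np
import pandas as pd
import pytest

from pcflow.stats import (
    NON_NORMAL,
    NORMAL,
    DegenerateDataError,
    covariate_precision_screen,
    f_test_variance,
    icc_absolute_single,
    ks_normality_gate,
    levene_rank,
    location_tests,
    mcnemar_exact,
    reclassification_summary,
)

# ---------------------------------------------------------------------------
# McNemar


def test_mcnemar_frozen_binomial_values():
    # full binomial enumeration: 2 * sum_{k<=2} C(11,k) / 2^11 = 2*(1+11+55)/2048
    assert mcnemar_exact(9, 2) == pytest.approx(2 * (1 + 11 + 55) / 2048, abs=1e-12)
    assert mcnemar_exact(10, 0) == pytest.approx(2 / 1024, abs=1e-12)


def test_mcnemar_symmetric_discordance_is_clamped_to_one():
    for k in (0, 1, 5, 20):
        assert mcnemar_exact(k, k) == 1.0


def test_mcnemar_is_symmetric_for_all_small_counts():
    for b in range(31):
        for c in range(31):
            assert mcnemar_exact(b, c) == mcnemar_exact(c, b)
            assert 0.0 <= mcnemar_exact(b, c) <= 1.0


def test_mcnemar_matches_statsmodels_exact():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    rng = np.random.default_rng(5)
    for _ in range(25):
        b, c = rng.integers(0, 15, size=2)
        if b + c == 0:
            continue
        table = [[10, b], [c, 10]]
        want = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar_exact(int(b), int(c)) == pytest.approx(want, abs=1e-10)


def test_mcnemar_rejects_negative_counts():
    with pytest.raises(ValueError):
        mcnemar_exact(-1, 3)


# ---------------------------------------------------------------------------
# variance tests


def test_f_test_of_sample_with_itself_is_one():
    x = np.random.default_rng(0).normal(size=30)
    assert f_test_variance(x, x) == pytest.approx(1.0)


def test_f_test_is_symmetric_in_its_arguments():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=30), rng.normal(scale=2.0, size=25)
    assert f_test_variance(x, y) == pytest.approx(f_test_variance(y, x), abs=1e-12)


def test_f_test_close_to_permutation_reference():
    """On normal data the F p-value tracks a label-permutation reference for
    the variance ratio."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    y = rng.normal(scale=1.35, size=30)
    p_f = f_test_variance(x, y)
    pooled = np.concatenate([x, y])
    obs = np.log(x.var(ddof=1) / y.var(ddof=1))
    stats = []
    for _ in range(20000):
        perm = rng.permutation(pooled)
        stats.append(np.log(perm[:30].var(ddof=1) / perm[30:].var(ddof=1)))
    p_perm = np.mean(np.abs(stats) >= abs(obs))
    assert p_f == pytest.approx(p_perm, abs=0.05)


def test_f_test_rejects_zero_variance():
    with pytest.raises(DegenerateDataError):
        f_test_variance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_rank_levene_on_identical_samples_is_one():
    x = np.array([1.0, 2.5, 3.0, 4.0, 7.0])
    assert levene_rank(x, x) == pytest.approx(1.0)


def test_rank_levene_detects_scale_difference():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        y = 3.0 * rng.normal(size=50)
        hits += levene_rank(x, y) < 0.05
    assert hits >= 90


def test_rank_levene_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=20), rng.normal(scale=2, size=25)
    p1 = levene_rank(x, y)
    p2 = levene_rank(np.exp(x), np.exp(y))  # strictly monotone on pooled data
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_rank_levene_rejects_all_tied_data():
    with pytest.raises(DegenerateDataError):
        levene_rank([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# ICC


def test_icc_perfect_agreement_is_one():
    m = np.column_stack([np.arange(10.0), np.arange(10.0)])
    assert icc_absolute_single(m) == pytest.approx(1.0)


def test_icc_anti_agreement_is_negative():
    r = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    m = np.column_stack([r, -r])
    assert icc_absolute_single(m) < 0


def _icc_anova_oracle(m):
    """Loop-based two-way ANOVA mean squares, ICC(A,1)."""
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    msr = sum(k * (rm - grand) ** 2 for rm in row_means) / (n - 1)
    msc = sum(n * (cm - grand) ** 2 for cm in col_means) / (k - 1)
    sse = sum(
        (m[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_equals_anova_oracle_on_random_matrices():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(3, 12))
        m = rng.normal(size=(n, 2))
        assert icc_absolute_single(m) == pytest.approx(
            _icc_anova_oracle(m), abs=1e-10
        )


def test_icc_matches_pingouin_absolute_single():
    import pingouin as pg

    rng = np.random.default_rng(9)
    base = rng.normal(size=12)
    m = np.column_stack([base, base + rng.normal(0, 0.3, size=12) + 0.1])
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "score": m.ravel(),
        }
    )
    icc_table = pg.intraclass_corr(df, "subject", "rater", "score")
    want = icc_table.set_index("Type").loc["ICC(A,1)", "ICC"]
    assert icc_absolute_single(m) == pytest.approx(want, abs=1e-9)


def test_icc_degenerate_matrix_is_rejected():
    with pytest.raises(DegenerateDataError):
        icc_absolute_single(np.full((5, 2), 3.0))


# ---------------------------------------------------------------------------
# normality gate and location tests


def test_gate_accepts_normal_samples():
    hits = sum(
        ks_normality_gate(np.random.default_rng(s).normal(size=500)) == NORMAL
        for s in range(100)
    )
    assert hits >= 95


def test_gate_rejects_exponential_samples():
    hits = sum(
        ks_normality_gate(np.random.default_rng(s).exponential(size=500)) == NON_NORMAL
        for s in range(100)
    )
    assert hits >= 95


def test_gate_flags_constant_sample_non_normal():
    assert ks_normality_gate(np.full(10, 1.0)) == NON_NORMAL


def test_identical_paired_samples_give_p_one():
    x = np.arange(10.0)
    assert location_tests(x, x, paired=True, gate=NORMAL) == 1.0
    assert location_tests(x, x, paired=True, gate=NON_NORMAL) == 1.0


def test_location_tests_detect_a_one_sd_shift():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        y = rng.normal(loc=1.0, size=50)
        hits += location_tests(x, y, paired=False, gate=NORMAL) < 0.05
    assert hits >= 90


def test_mann_whitney_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    x, y = rng.normal(size=30), rng.normal(loc=0.5, size=35)
    p1 = location_tests(x, y, paired=False, gate=NON_NORMAL)
    p2 = location_tests(np.exp(x), np.exp(y), paired=False, gate=NON_NORMAL)
    assert p1 == pytest.approx(p2, abs=1e-12)


# ---------------------------------------------------------------------------
# covariate screen


def _null_table(seed, n=40):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"qpqs": rng.normal(1.0, 0.1, size=n), "cov": rng.normal(size=n)}
    )


def test_screen_uses_bonferroni_threshold():
    rep = covariate_precision_screen(_null_table(0), ["cov"], "qpqs")
    assert rep.loc[0, "alpha_adjusted"] == pytest.approx(0.05 / 20)


def test_screen_skips_constant_covariate_with_warning():
    table = _null_table(1)
    table["flat"] = 1.0
    with pytest.warns(UserWarning, match="flat"):
        rep = covariate_precision_screen(table, ["flat"], "qpqs")
    assert bool(rep.loc[0, "skipped"])


def test_screen_type_one_error_is_controlled_at_unadjusted_level():
    """A covariate independent of Qp/Qs is flagged at the *unadjusted* 0.05
    level in roughly <= 5% of seeded null cohorts."""
    flags = 0
    for seed in range(200):
        rep = covariate_precision_screen(_null_table(seed), ["cov"], "qpqs", m=1)
        flags += bool(rep.loc[0, "significant"])
    assert flags <= 0.05 * 200 + 2 * np.sqrt(200 * 0.05 * 0.95)  # ~5% + 2 SE


# ---------------------------------------------------------------------------
# reclassification


def test_identical_label_vectors_change_nothing():
    labels = ["normal"] * 10 + ["left-to-right"] * 2
    s = reclassification_summary(labels, labels)
    assert s.counts.b == s.counts.c == 0
    assert s.pct_pathological_before == s.pct_pathological_after
    assert s.mcnemar_p == 1.0


def test_printed_count_scenario_reproduces_percentages():
    """16 of 91 pathological before; 7 remain pathological and 2 become
    newly pathological after: 18% -> 10%, 9/16 = 56% normalized."""
    before = ["left-to-right"] * 16 + ["normal"] * 75
    after = (
        ["left-to-right"] * 7
        + ["normal"] * 9
        + ["left-to-right"] * 2
        + ["normal"] * 73
    )
    s = reclassification_summary(before, after)
    assert (s.counts.a, s.counts.b, s.counts.c, s.counts.d) == (73, 9, 2, 7)
    assert s.pct_pathological_before == 18
    assert s.pct_pathological_after == 10
    assert s.normalized_fraction == pytest.approx(9 / 16)
    assert s.pct_normalized == 56


def test_all_normal_before_has_undefined_normalized_fraction():
    s = reclassification_summary(["normal"] * 5, ["normal"] * 4 + ["left-to-right"])
    assert s.normalized_fraction is None
    assert s.pct_normalized is None


def test_length_mismatch_is_rejected():
    with pytest.raises(ValueError):
        reclassification_summary(["normal"], ["normal", "normal"])
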