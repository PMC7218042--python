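"""Agreement statistics against brute-force and third-party oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y90agree.agreement import (
    ReadingsMatrix,
    bland_altman,
    compare_readers,
    icc,
    normal_range_quantile,
    pairwise_cv,
    rdc,
    two_way_mean_squares,
)

# 6x3 worked matrix (three observers reading six treatments)
WORKED_6x3 = np.array(
    [
        [181.0, 204.0, 190.0],
        [45.0, 52.0, 48.0],
        [320.0, 290.0, 305.0],
        [99.0, 101.0, 95.0],
        [410.0, 455.0, 430.0],
        [150.0, 158.0, 161.0],
    ]
)

# 8x3 matrix without ties for the Friedman rank-sum oracle
FRIEDMAN_8x3 = np.array(
    [
        [1.2, 2.1, 0.9],
        [3.4, 3.9, 3.1],
        [5.5, 6.2, 5.1],
        [2.2, 2.9, 2.0],
        [7.7, 8.5, 7.2],
        [4.4, 4.1, 4.6],
        [6.6, 7.3, 6.1],
        [0.5, 1.1, 0.4],
    ]
)


def make_matrix(values: np.ndarray) -> ReadingsMatrix:
    n, k = values.shape
    return ReadingsMatrix(
        values=values,
        observer_labels=tuple("ABCDEFG"[:k]),
        treatment_labels=tuple(f"T{i}" for i in range(n)),
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def icc_a1_bruteforce(x: np.ndarray) -> float:
    """ICC(A,1) from mean squares computed by explicit double sums."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_matches_bruteforce_mean_squares_on_worked_matrix():
    res = icc(make_matrix(WORKED_6x3))
    assert res.estimate == pytest.approx(icc_a1_bruteforce(WORKED_6x3), abs=1e-12)


def test_icc_matches_pingouin_icc2_estimate_and_ci():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    n, k = WORKED_6x3.shape
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": WORKED_6x3.ravel(),
        }
    )
    ref = pingouin.intraclass_corr(
        long, targets="targets", raters="raters", ratings="ratings"
    )
    row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    res = icc(make_matrix(WORKED_6x3))
    assert res.estimate == pytest.approx(row["ICC"], abs=1e-6)
    ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
    lo, hi = row[ci_col]
    # pingouin rounds its CI bounds to 2 decimals
    assert res.ci_low == pytest.approx(lo, abs=0.01)
    assert res.ci_high == pytest.approx(hi, abs=0.01)


def test_icc_perfect_agreement_is_one():
    rows = np.array([[10.0], [20.0], [35.0], [50.0], [70.0]])
    res = icc(make_matrix(np.repeat(rows, 3, axis=1)))
    assert res.estimate == 1.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)


def test_icc_pure_noise_is_near_zero():
    rng = np.random.default_rng(0)
    res = icc(make_matrix(rng.normal(100.0, 10.0, size=(4000, 3))))
    assert abs(res.estimate) < 0.05


def test_icc_invariant_under_common_affine_transform():
    a = icc(make_matrix(WORKED_6x3)).estimate
    b = icc(make_matrix(3.5 * WORKED_6x3 + 40.0)).estimate
    assert b == pytest.approx(a, abs=1e-10)
    assert a <= 1.0


def test_icc_errors_and_flags():
    with pytest.raises(ValueError, match="zero total variance"):
        icc(make_matrix(np.full((6, 3), 5.0)))
    low_n = icc(make_matrix(WORKED_6x3[:4]))
    assert low_n.low_n
    assert not icc(make_matrix(WORKED_6x3)).low_n


def test_icc_works_on_column_subsets():
    m = make_matrix(WORKED_6x3)
    for pair in itertools.combinations("ABC", 2):
        res = icc(m.subset(pair))
        assert res.ci_low <= res.estimate <= res.ci_high <= 1.0


# ---------------------------------------------------------------------------
# pairwise CV
# ---------------------------------------------------------------------------


def test_cv_single_pair_worked_example():
    # s = 21/sqrt(2), m = 110.5 -> 100*s/m = 13.44
    assert pairwise_cv([100.0], [121.0]) == pytest.approx(13.44, abs=0.005)


def test_cv_identical_series_is_zero():
    x = np.array([3.0, 7.0, 11.0])
    assert pairwise_cv(x, x) == 0.0


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(1.0, 1e4), min_size=2, max_size=20),
    st.floats(0.01, 1000.0),
)
def test_cv_is_scale_invariant(values, scale):
    x = np.array(values)
    y = x * 1.07 + 0.5
    assert pairwise_cv(x * scale, y * scale) == pytest.approx(
        pairwise_cv(x, y), rel=1e-9
    )


def test_cv_rejects_nonpositive_values():
    with pytest.raises(ValueError):
        pairwise_cv([1.0, -2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


def test_bland_altman_identical_series():
    x = np.array([1.0, 2.0, 3.0])
    res = bland_altman(x, x)
    assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)


def test_bland_altman_constant_difference():
    x = np.array([10.0, 20.0, 30.0])
    res = bland_altman(x + 4.0, x)
    assert res.bias == pytest.approx(4.0)
    assert res.sd_diff == 0.0
    assert res.loa_low == res.loa_high == pytest.approx(4.0)


def test_bland_altman_uses_multiplier_two():
    rng = np.random.default_rng(1)
    x = rng.normal(50, 5, 100)
    y = x + rng.normal(0, 2, 100)
    res = bland_altman(x, y)
    d = x - y
    assert res.loa_high == pytest.approx(d.mean() + 2 * d.std(ddof=1))
    assert res.n == 100
    assert np.allclose(res.means, (x + y) / 2)


# ---------------------------------------------------------------------------
# RDC
# ---------------------------------------------------------------------------


def test_normal_range_quantile_k2_closed_form():
    # range of 2 normals is |N(0, 2)|: q95 = sqrt(2) * z_{0.975}
    assert normal_range_quantile(2) == pytest.approx(
        math.sqrt(2) * 1.959963985, abs=1e-6
    )


def test_rdc_identical_columns_is_exactly_one():
    rows = np.array([[10.0], [20.0], [35.0], [50.0]])
    res = rdc(make_matrix(np.repeat(rows, 3, axis=1)))
    assert res.estimate == 1.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)
    assert res.sigma_within_log == 0.0


def test_rdc_scale_invariance_and_bound():
    res1 = rdc(make_matrix(WORKED_6x3), seed=0)
    res2 = rdc(make_matrix(WORKED_6x3 * 1000.0), seed=0)
    assert res1.estimate == pytest.approx(res2.estimate, rel=1e-12)
    assert res1.estimate >= 1.0
    assert res1.ci_low <= res1.estimate <= res1.ci_high
    assert res1.estimate == pytest.approx(
        math.exp(res1.q95_range_k * res1.sigma_within_log)
    )


def test_rdc_invariant_to_observer_permutation():
    m = make_matrix(WORKED_6x3)
    perm = make_matrix(WORKED_6x3[:, [2, 0, 1]])
    assert rdc(m, seed=0).estimate == pytest.approx(rdc(perm, seed=0).estimate)


def test_rdc_increases_with_observer_noise():
    rng = np.random.default_rng(5)
    base = np.exp(rng.normal(5.0, 0.4, size=(200, 1)))
    estimates = []
    for sigma in (0.02, 0.08, 0.2):
        noisy = base * np.exp(rng.normal(0.0, sigma, size=(200, 3)))
        estimates.append(rdc(make_matrix(noisy), seed=1).estimate)
    assert estimates[0] < estimates[1] < estimates[2]


def test_rdc_bootstrap_is_seed_deterministic():
    m = make_matrix(WORKED_6x3)
    a, b = rdc(m, seed=42), rdc(m, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    c = rdc(m, seed=43)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


def test_rdc_rejects_nonpositive_values():
    bad = WORKED_6x3.copy()
    bad[0, 0] = 0.0
    with pytest.raises(ValueError):
        rdc(make_matrix(bad))


# ---------------------------------------------------------------------------
# location tests
# ---------------------------------------------------------------------------


def test_parametric_family_chosen_for_normal_columns_with_offsets():
    rng = np.random.default_rng(2)
    base = rng.normal(100.0, 10.0, 30)
    x = np.column_stack([base, base + 5.0, base + 5.0 + rng.normal(0, 0.5, 30)])
    res = compare_readers(make_matrix(x))
    assert res.family == "parametric"
    assert res.overall_test == "two-way ANOVA (observer effect)"
    ab = next(p for p in res.pairwise if p.pair == ("A", "B"))
    assert ab.p_value is not None and ab.p_value < 1e-6
    assert res.overall_p < 1e-6


def test_nonparametric_family_chosen_for_skewed_columns():
    rng = np.random.default_rng(3)
    base = np.exp(rng.normal(3.0, 1.2, 40))
    x = np.column_stack([base, base * 1.1, base * 0.9]) * np.exp(
        rng.normal(0, 0.05, (40, 3))
    )
    res = compare_readers(make_matrix(x))
    assert res.family == "non-parametric"
    assert res.overall_test == "Friedman"
    assert all(p.p_value is not None for p in res.pairwise)


def test_identical_columns_take_the_degenerate_path():
    rows = np.array([[10.0], [20.0], [35.0], [50.0], [70.0]])
    res = compare_readers(make_matrix(np.repeat(rows, 3, axis=1)))
    assert res.degenerate
    assert res.overall_p is None
    assert all(p.degenerate for p in res.pairwise)


def friedman_bruteforce(x: np.ndarray) -> float:
    """Friedman chi-square from first-principles rank sums (no ties)."""
    n, k = x.shape
    ranks = np.zeros_like(x)
    for i in range(n):
        order = sorted(range(k), key=lambda j: x[i, j])
        for rank0, j in enumerate(order):
            ranks[i, j] = rank0 + 1
    rank_sums = ranks.sum(axis=0)
    return float(
        12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    )


def test_friedman_statistic_matches_rank_sum_oracle():
    res = compare_readers(make_matrix(FRIEDMAN_8x3))
    expected = friedman_bruteforce(FRIEDMAN_8x3)
    if res.family == "non-parametric":
        assert res.overall_statistic == pytest.approx(expected, abs=1e-9)
    else:  # gate chose parametric for this fixture: compute Friedman directly
        from scipy.stats import friedmanchisquare

        stat = friedmanchisquare(*FRIEDMAN_8x3.T).statistic
        assert stat == pytest.approx(expected, abs=1e-9)


def test_observer_effect_anova_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.api")
    import pandas as pd
    from statsmodels.formula.api import ols

    x = WORKED_6x3
    n, k = x.shape
    long = pd.DataFrame(
        {
            "y": x.ravel(),
            "treatment": np.repeat([f"t{i}" for i in range(n)], k),
            "observer": np.tile([f"o{j}" for j in range(k)], n),
        }
    )
    fit = ols("y ~ C(treatment) + C(observer)", data=long).fit()
    table = statsmodels.stats.anova_lm(fit, typ=2)
    res = compare_readers(make_matrix(x))
    # the gate may route this fixture either way; test the ANOVA part directly
    from y90agree.agreement import _observer_effect_anova

    f, p = _observer_effect_anova(x)
    assert f == pytest.approx(table.loc["C(observer)", "F"], rel=1e-9)
    assert p == pytest.approx(table.loc["C(observer)", "PR(>F)"], rel=1e-9)


def test_mean_squares_identity():
    """SSR + SSC + SSE partitions the total sum of squares."""
    x = WORKED_6x3
    n, k = x.shape
    msr, msc, mse = two_way_mean_squares(x)
    sst = np.sum((x - x.mean()) ** 2)
    assert msr * (n - 1) + msc * (k - 1) + mse * (n - 1) * (k - 1) == pytest.approx(
        sst
    )


def test_matrix_validation():
    with pytest.raises(ValueError):
        make_matrix(np.array([[1.0, 2.0]]))  # n < 2
    with pytest.raises(ValueError):
        make_matrix(np.array([[1.0], [2.0]]))  # k < 2
    with pytest.raises(ValueError):
        make_matrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
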