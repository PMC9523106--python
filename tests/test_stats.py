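import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from hemoqol.exceptions import InsufficientDataError, ValidationError
from hemoqol.stats import (
    ModelResult,
    compare_distributions,
    little_mcar,
    mice_impute,
    mixed_association,
    regression_power,
    required_n,
    rubin_pool,
    summarize_changes,
)

# ---------------------------------------------------------------------------
# independent oracles


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = lambda k: sst.hypergeom.pmf(k, n, r1, c1)  # noqa: E731
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(0, min(r1, c1) + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def signed_rank_oracle(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sst.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = n * (n + 1) / 2
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws, float)
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    return float(np.mean((ws <= lo + 1e-9) | (ws >= hi - 1e-9)))


# ---------------------------------------------------------------------------
# change table


def test_paired_t_closed_form_n3():
    cohort = pd.DataFrame({"v_pre": [1.0, 2.0, 4.0], "v_post": [2.0, 3.0, 3.0]})
    row = summarize_changes(cohort, "v")
    assert row["mean_change"] == pytest.approx(1.0 / 3.0)
    # t = 0.5 with df = 2: two-sided p = 1 - t/sqrt(2 + t^2) = 2/3 exactly
    assert row["p_value"] == pytest.approx(2.0 / 3.0, abs=1e-9)
    tcrit = sst.t.ppf(0.975, 2)
    se = np.std([1, 1, -1], ddof=1) / np.sqrt(3)
    assert row["ci_low"] == pytest.approx(1 / 3 - tcrit * se)
    assert row["ci_high"] == pytest.approx(1 / 3 + tcrit * se)


def test_identical_columns_give_p_one():
    cohort = pd.DataFrame({"v_pre": [1.0, 2.0, 3.0, 4.0], "v_post": [1.0, 2.0, 3.0, 4.0]})
    row = summarize_changes(cohort, "v")
    assert row["mean_change"] == 0.0
    assert row["p_value"] == 1.0


def test_summarize_needs_three_pairs():
    cohort = pd.DataFrame({"v_pre": [1.0, 2.0, np.nan], "v_post": [2.0, 3.0, 4.0]})
    with pytest.raises(InsufficientDataError):
        summarize_changes(cohort, "v")


def test_percent_change_is_mean_of_per_patient_percents():
    cohort = pd.DataFrame({"v_pre": [100.0, 200.0], "v_post": [150.0, 220.0]})
    with pytest.raises(InsufficientDataError):
        summarize_changes(cohort, "v")
    cohort = pd.DataFrame({"v_pre": [100.0, 200.0, 400.0], "v_post": [150.0, 220.0, 400.0]})
    row = summarize_changes(cohort, "v")
    assert row["pct_change"] == pytest.approx((50 + 10 + 0) / 3.0)


# ---------------------------------------------------------------------------
# rank and exact tests


@pytest.mark.parametrize("table", [[[3, 1], [1, 3]], [[8, 2], [1, 5]], [[5, 0], [0, 5]], [[2, 2], [2, 2]]])
def test_fisher_matches_enumeration(table):
    res = compare_distributions(table, None, kind="exact_2x2")
    assert res.p_value == pytest.approx(fisher_oracle(table), abs=1e-9)


def test_fisher_known_value():
    res = compare_distributions([[3, 1], [1, 3]], None, kind="exact_2x2")
    assert res.p_value == pytest.approx(0.4857, abs=1e-4)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_signed_rank_matches_enumeration_small_n(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 11))
    x = rng.normal(0.3, 1.0, n)
    y = np.zeros(n)
    res = compare_distributions(x, y, design="paired", kind="rank")
    assert res.p_value == pytest.approx(signed_rank_oracle(x, y), abs=1e-9)


def test_paired_identical_gives_p_one():
    x = np.arange(8.0)
    res = compare_distributions(x, x, design="paired", kind="rank")
    assert res.p_value == 1.0


def test_rank_sum_separated_samples():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 20)
    res = compare_distributions(x, x + 10.0, design="independent", kind="rank")
    assert res.p_value < 1e-3


# ---------------------------------------------------------------------------
# mixed model


def _toy_cohort(n=40, beta=-0.002, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    pre = rng.uniform(0.4, 0.9, n)
    x = rng.normal(-10.0, 30.0, n)
    post = pre + beta * x + rng.normal(0.0, noise, n)
    return pd.DataFrame({"hrqol_pre": pre, "hrqol_post": post, "delta_lvet": x})


def test_mixed_association_noiseless_recovery():
    df = _toy_cohort(noise=1e-8)
    res = mixed_association(df)
    assert res.estimate == pytest.approx(0.02, abs=1e-4)  # -0.002/ms * -10 ms
    assert res.p_value < 1e-6


def test_mixed_association_delta_form_equals_ols():
    df = _toy_cohort(noise=0.05, seed=3)
    res = mixed_association(df, model_form="delta")
    slope = sst.linregress(df.delta_lvet, df.hrqol_post - df.hrqol_pre)
    assert res.estimate == pytest.approx(slope.slope * -10.0)


def test_mixed_association_needs_twenty_patients():
    with pytest.raises(InsufficientDataError):
        mixed_association(_toy_cohort(n=10))


# ---------------------------------------------------------------------------
# missing data


def test_little_complete_data_convention():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)))
    res = little_mcar(df)
    assert res.estimate == 0.0 and res.p_value == 1.0


def test_little_rejects_strong_mar():
    rng = np.random.default_rng(4)
    rej = 0
    for _ in range(50):
        x = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=200)
        drop = rng.random(200) < sst.norm.cdf(2.0 * x[:, 0]) * 0.5
        x[drop, 1] = np.nan
        rej += little_mcar(pd.DataFrame(x)).p_value < 0.05
    assert rej / 50 > 0.5


def test_little_all_missing_variable_errors():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
    with pytest.raises(ValidationError):
        little_mcar(df)


def test_mice_no_missing_is_identity():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)), columns=list("abc"))
    out = mice_impute(df, m=3, seed=1)
    assert len(out) == 3
    for comp in out:
        pd.testing.assert_frame_equal(comp, df)


def test_mice_deterministic_under_seed():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    df.loc[rng.random(60) < 0.15, "b"] = np.nan
    a = mice_impute(df, m=2, iters=3, seed=42)
    b = mice_impute(df, m=2, iters=3, seed=42)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
        assert not x.isna().any().any()


def test_mice_refuses_heavy_missingness():
    df = pd.DataFrame({"a": [1.0, np.nan, np.nan, np.nan], "b": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValidationError):
        mice_impute(df)


def test_rubin_pooling_oracle():
    res = rubin_pool([
        ModelResult(1.0, 0.5, None, None, 0.5, 10, "m"),
        ModelResult(2.0, 0.5, None, None, 0.5, 10, "m"),
    ])
    assert res.estimate == pytest.approx(1.5)
    # total variance = 0.25 + (1 + 1/2) * 0.5 = 1.0
    assert res.se == pytest.approx(1.0)


def test_rubin_zero_between_equals_complete_data():
    r = ModelResult(0.7, 0.1, None, None, 0.02, 30, "m")
    pooled = rubin_pool([r, r, r])
    assert pooled.estimate == r.estimate
    assert pooled.se == pytest.approx(r.se)
    assert pooled.p_value == r.p_value


# ---------------------------------------------------------------------------
# power


def test_power_at_planned_sample_size():
    assert regression_power(f2=0.2, u=10, alpha=0.05, n=91) >= 0.80


def test_power_null_limit_is_alpha():
    assert regression_power(f2=1e-9, u=5, alpha=0.05, n=100) == pytest.approx(0.05, abs=1e-3)


def test_power_monotone_in_n_and_decreasing_in_u():
    grid = [regression_power(0.2, 10, 0.05, n) for n in range(30, 200, 10)]
    assert all(b > a for a, b in zip(grid, grid[1:]))
    by_u = [regression_power(0.2, u, 0.05, 100) for u in (2, 5, 10, 20)]
    assert all(b < a for a, b in zip(by_u, by_u[1:]))


def test_required_n_inverse_consistency():
    n = required_n(f2=0.2, u=10, alpha=0.05, target_power=0.80)
    assert regression_power(0.2, 10, 0.05, n) >= 0.80
    assert regression_power(0.2, 10, 0.05, n - 1) < 0.80
    assert n <= 91


def test_power_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        regression_power(0.0, 5, 0.05, 50)
    with pytest.raises(ValidationError):
        regression_power(0.2, 10, 0.05, 11)


def test_model_result_invariants():
    with pytest.raises(ValidationError):
        ModelResult(5.0, 1.0, 1.0, 2.0, 0.5, 10, "m")
    with pytest.raises(ValidationError):
        ModelResult(1.0, 1.0, 0.0, 2.0, 1.5, 10, "m")
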