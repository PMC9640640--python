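import numpy as np
import pytest
from scipy import stats as ss

from _oracles import friedman_statistic_bruteforce, ks_statistic_ecdf
from iolcalib import (
    PowerSpec,
    bland_altman,
    friedman_bonferroni,
    ks_normality,
    one_sample_t,
    paired_t,
    paired_t_power,
    paired_t_sample_size,
)


# ---------------------------------------------------------------- t-tests

def test_paired_t_zero_difference():
    x = [1.0, 2.0, 3.0]
    res = paired_t(x, x)
    assert (res.statistic, res.p_value, res.df) == (0.0, 1.0, 2)


def test_paired_t_constant_nonzero_difference_raises():
    with pytest.raises(ValueError, match="sd = 0"):
        paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def test_paired_t_hand_computed_case():
    # textbook formula: t = mean(d) / (sd(d)/sqrt(n)), d = x - y
    res = paired_t([1.0, 2.0, 3.0, 4.0], [1.1, 2.3, 2.8, 4.4])
    assert res.statistic == pytest.approx(-1.1338934190, abs=1e-9)
    assert res.p_value == pytest.approx(0.3392540509, abs=1e-9)
    assert res.df == 3


def test_paired_t_sign_flip_invariance():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)
    assert paired_t(x, y).p_value == pytest.approx(paired_t(y, x).p_value, abs=1e-12)


def test_one_sample_t_cases():
    assert one_sample_t([2.0, 2.0, 2.0], 2.0).p_value == 1.0
    with pytest.raises(ValueError):
        one_sample_t([2.0, 2.0, 2.0], 1.0)
    res = one_sample_t([1.0, 2.0, 3.0, 4.0], 2.0)
    assert res.statistic == pytest.approx(0.7745966692, abs=1e-9)
    assert res.p_value == pytest.approx(0.4950253461, abs=1e-9)


def test_paired_t_type_one_error_calibrated():
    """1,000 null simulations (paired normals, n=50) reject at 5% +/- 1.5%."""
    rng = np.random.default_rng(12345)
    x = rng.normal(0.0, 1.0, (1000, 50))
    y = rng.normal(0.0, 1.0, (1000, 50))
    rate = float((ss.ttest_rel(x, y, axis=1).pvalue < 0.05).mean())
    # cross-check a handful against the package's scalar implementation
    for i in range(5):
        assert paired_t(x[i], y[i]).p_value == pytest.approx(
            float(ss.ttest_rel(x[i], y[i]).pvalue), abs=1e-12
        )
    assert 0.035 <= rate <= 0.065


# ---------------------------------------------------------------- Friedman

def test_friedman_identical_columns():
    overall, pairwise = friedman_bonferroni([[1, 1, 1]] * 4)
    assert (overall.statistic, overall.p_value) == (0.0, 1.0)
    assert all(p == 1.0 for p in pairwise.values())


def test_friedman_matches_bruteforce_ranks():
    mat = [[1, 2, 3], [1, 2, 3], [2, 1, 3], [1, 3, 2]]
    overall, _ = friedman_bonferroni(mat)
    assert overall.statistic == pytest.approx(friedman_statistic_bruteforce(mat), abs=1e-12)
    assert overall.statistic == pytest.approx(4.5, abs=1e-12)
    # and against the library implementation on a tie-free matrix
    scipy_stat, scipy_p = ss.friedmanchisquare(*np.array(mat).T.tolist())
    assert overall.statistic == pytest.approx(scipy_stat, abs=1e-12)
    assert overall.p_value == pytest.approx(scipy_p, abs=1e-12)


def test_friedman_bonferroni_cap():
    mat = [[1, 2, 3], [1, 2, 3], [2, 1, 3], [1, 3, 2]]
    _, pairwise = friedman_bonferroni(mat)
    assert pairwise[(0, 1)] == pytest.approx(min(1.0, 0.8665330990), abs=1e-9)
    assert pairwise[(0, 2)] == pytest.approx(0.1016845606, abs=1e-9)
    assert all(0.0 <= p <= 1.0 for p in pairwise.values())


def test_friedman_row_monotone_invariance():
    rng = np.random.default_rng(5)
    mat = rng.normal(0, 1, (12, 3))
    base, _ = friedman_bonferroni(mat)
    transformed = mat.copy()
    transformed[3] = np.exp(transformed[3])  # monotone map of one whole row
    after, _ = friedman_bonferroni(transformed)
    assert after.statistic == pytest.approx(base.statistic, abs=1e-12)


def test_friedman_rejects_missing_cells():
    with pytest.raises(ValueError):
        friedman_bonferroni([[1.0, np.nan, 2.0], [1.0, 2.0, 3.0]])


# ---------------------------------------------------------------- KS normality

def test_ks_statistic_matches_ecdf_oracle():
    x = np.array([0.0, 0.5, 1.0, 1.5, 3.0])
    res = ks_normality(x)
    assert res.statistic == pytest.approx(
        ks_statistic_ecdf(x, x.mean(), x.std(ddof=1)), abs=1e-12
    )
    assert res.statistic == pytest.approx(0.1971914922, abs=1e-9)


def test_ks_accepts_normal_samples():
    accepted = sum(
        ks_normality(np.random.default_rng(seed).normal(0, 1, 200)).p_value > 0.05
        for seed in range(100)
    )
    assert accepted >= 95


def test_ks_lilliefors_rejects_uniform():
    x = np.random.default_rng(11).uniform(0, 1, 200)
    assert ks_normality(x, lilliefors=True).p_value < 0.05


def test_ks_requires_minimum_n():
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0, 3.0, 4.0])


# ---------------------------------------------------------------- Bland-Altman

def test_bland_altman_zero_and_shift():
    x = np.linspace(20, 30, 10)
    ba = bland_altman(x, x)
    assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)
    ba = bland_altman(x + 0.11, x)
    assert ba.bias == pytest.approx(0.11, abs=1e-12)
    assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)


def test_bland_altman_loa_structure():
    rng = np.random.default_rng(9)
    x, y = rng.normal(23.6, 1.3, 80), rng.normal(23.5, 1.3, 80)
    ba = bland_altman(x, y)
    assert ba.loa_low == pytest.approx(ba.bias - 1.96 * ba.sd_diff, abs=1e-12)
    assert ba.loa_high == pytest.approx(ba.bias + 1.96 * ba.sd_diff, abs=1e-12)


def test_bland_altman_recovers_generator_offsets(default_cohort, default_params):
    ops = [r for r in default_cohort if r.eye_role == "operated"]
    ba = bland_altman(
        [r.al_post_pseudophakic for r in ops], [r.al_pre_phakic for r in ops]
    )
    n = len(ops)
    tol = 3 * default_params.paired_noise_sd / np.sqrt(n)
    assert ba.bias == pytest.approx(-default_params.mode_offsets.phakic, abs=tol)
    assert ba.sd_diff == pytest.approx(default_params.paired_noise_sd, rel=0.25)


# ---------------------------------------------------------------- sample size

def test_sample_size_matches_study_design():
    spec = PowerSpec(delta=0.02, sigma=0.08, alpha=0.05, power=0.80)
    n = paired_t_sample_size(spec)
    z_bound = int(np.ceil(((ss.norm.ppf(0.975) + ss.norm.ppf(0.8)) * 0.08 / 0.02) ** 2))
    assert z_bound == 126
    assert n == 128
    assert n >= z_bound
    assert paired_t_power(n, spec) >= 0.80 > paired_t_power(n - 1, spec)


def test_sample_size_scales_inversely_with_delta_squared():
    n = paired_t_sample_size(PowerSpec(delta=0.04, sigma=0.08))
    assert 30 <= n <= 36


def test_sample_size_monotonicity():
    base = paired_t_sample_size(PowerSpec(delta=0.05, sigma=0.10))
    assert paired_t_sample_size(PowerSpec(delta=0.06, sigma=0.10)) <= base
    assert paired_t_sample_size(PowerSpec(delta=0.05, sigma=0.12)) >= base
    assert paired_t_sample_size(PowerSpec(delta=0.05, sigma=0.10, power=0.9)) >= base


def test_power_spec_validation():
    with pytest.raises(ValueError):
        PowerSpec(delta=0.0, sigma=0.08)
    with pytest.raises(ValueError):
        PowerSpec(delta=0.02, sigma=0.08, alpha=1.5)
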