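import numpy as np
import pytest
from scipy import stats

from conftest import make_harmonized, random_harmonized, weighted_median_oracle, wls_oracle
from mrmediate.estimators import (
    funnel_data,
    ivw,
    leave_one_out,
    mr_egger,
    wald_ratio,
    weighted_median,
)


# --------------------------------------------------------------- Wald ratio


def test_wald_ratio_basics():
    assert wald_ratio(0.2, 0.01, 0.1, 0.05).beta == pytest.approx(0.5)
    est = wald_ratio(0.1, 0.01, 0.3, 0.05)
    assert est.se == pytest.approx(0.5)
    null = wald_ratio(0.2, 0.01, 0.0, 0.05)
    assert null.beta == 0.0 and null.pval == pytest.approx(1.0)
    with pytest.raises(ValueError):
        wald_ratio(0.0, 0.01, 0.1, 0.05)


# ---------------------------------------------------------------------- IVW


def test_ivw_perfect_proportionality_gives_zero_q():
    bx = np.array([0.02, 0.05, 0.08])
    h = make_harmonized(bx, 0.5 * bx, [0.01, 0.01, 0.01])
    est, q = ivw(h)
    assert est.beta == pytest.approx(0.5)
    assert q.Q == pytest.approx(0.0, abs=1e-20)


def test_ivw_single_snp_falls_back_to_wald():
    h = make_harmonized([0.05], [0.02], [0.01])
    est, q = ivw(h)
    ref = wald_ratio(0.05, 1e-6, 0.02, 0.01)
    assert est.beta == pytest.approx(ref.beta) and est.se == pytest.approx(ref.se)
    assert q.df == 0


@pytest.mark.parametrize("seed", range(5))
def test_ivw_matches_wls_through_origin_oracle(seed):
    h = random_harmonized(np.random.default_rng(seed), n_snp=10)
    w = h.se_outcome**-2
    b, se, q = wls_oracle(h.beta_exposure[:, None], h.beta_outcome, w)
    est_f, qres = ivw(h, "fixed")
    assert est_f.beta == pytest.approx(b[0], rel=1e-10)
    assert est_f.se == pytest.approx(se[0], rel=1e-10)
    assert qres.Q == pytest.approx(q, rel=1e-10)
    est_r, _ = ivw(h, "multiplicative_random")
    assert est_r.se == pytest.approx(se[0] * max(1, np.sqrt(q / (h.n_snp - 1))), rel=1e-10)
    assert est_r.se >= est_f.se  # random-effects never shrinks the SE


# ----------------------------------------------------------------- MR-Egger


@pytest.mark.parametrize("seed", range(5))
def test_egger_matches_wls_with_intercept_oracle(seed):
    h = random_harmonized(np.random.default_rng(100 + seed), n_snp=15)
    est, intercept, q = mr_egger(h)
    flip = np.sign(h.beta_exposure)
    X = np.column_stack([np.ones(h.n_snp), h.beta_exposure * flip])
    b, se, q_o = wls_oracle(X, h.beta_outcome * flip, h.se_outcome**-2)
    factor = max(1, np.sqrt(q_o / (h.n_snp - 2)))
    assert est.beta == pytest.approx(b[1], rel=1e-10)
    assert intercept.intercept == pytest.approx(b[0], rel=1e-10)
    assert est.se == pytest.approx(se[1] * factor, rel=1e-10)
    assert intercept.se == pytest.approx(se[0] * factor, rel=1e-10)
    assert q.Q == pytest.approx(q_o, rel=1e-10)


def test_egger_recovers_planted_intercept_at_negligible_noise():
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.02, 0.08, 30)
    by = 0.05 + 0.4 * bx + rng.normal(0, 1e-6, 30)
    h = make_harmonized(bx, by, np.full(30, 0.005))
    est, intercept, _ = mr_egger(h)
    assert intercept.intercept == pytest.approx(0.05, abs=1e-4)
    assert est.beta == pytest.approx(0.4, abs=1e-3)


def test_egger_requires_three_snps():
    with pytest.raises(ValueError):
        mr_egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


def test_egger_intercept_type1_error_under_balanced_pleiotropy():
    """With InSIDE satisfied and zero-mean pleiotropy the intercept test
    should reject at roughly its nominal 5% level."""
    rng = np.random.default_rng(11)
    n_rep, n_snp = 400, 50
    rej = 0
    for _ in range(n_rep):
        bx = rng.uniform(0.02, 0.08, n_snp)
        sy = np.full(n_snp, 0.006)
        a = rng.normal(0, 0.006, n_snp)  # balanced pleiotropy
        by = 0.3 * bx + a + rng.normal(0, sy)
        _, intercept, _ = mr_egger(make_harmonized(bx, by, sy))
        rej += intercept.pval < 0.05
    assert 0.02 <= rej / n_rep <= 0.09


# ---------------------------------------------------------- weighted median


def test_weighted_median_degenerate_and_middle_cases():
    bx = np.array([0.05, 0.05, 0.05])
    h = make_harmonized(bx, 0.7 * bx, [0.01, 0.01, 0.01])
    assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.7)
    h = make_harmonized(bx, bx * np.array([0.1, 0.5, 0.9]), [0.01, 0.01, 0.01])
    assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(4))
def test_weighted_median_matches_interpolation_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    h = random_harmonized(rng, n_snp=5)
    est = weighted_median(h, n_boot=50, seed=0)
    ratios = h.beta_outcome / h.beta_exposure
    weights = (h.beta_exposure / h.se_outcome) ** 2
    assert est.beta == pytest.approx(weighted_median_oracle(ratios, weights), rel=1e-12)


def test_weighted_median_excludes_zero_bx():
    h = make_harmonized([0.0, 0.05, 0.06, 0.04], [0.1, 0.025, 0.03, 0.02], [0.01] * 4)
    est = weighted_median(h, n_boot=50, seed=0)
    assert est.n_snp == 3
    assert est.beta == pytest.approx(0.5)


def test_weighted_median_bootstrap_is_seeded():
    h = random_harmonized(np.random.default_rng(9), n_snp=8)
    a = weighted_median(h, n_boot=200, seed=5)
    b = weighted_median(h, n_boot=200, seed=5)
    assert a.se == b.se


# --------------------------------------------------- sign-flip invariance


@pytest.mark.parametrize("seed", range(3))
def test_estimators_invariant_to_per_snp_sign_flips(seed):
    rng = np.random.default_rng(300 + seed)
    h = random_harmonized(rng, n_snp=12)
    flip = rng.choice([-1.0, 1.0], 12)
    h2 = make_harmonized(
        h.beta_exposure * flip, h.beta_outcome * flip, h.se_outcome, sx=h.se_exposure
    )
    assert ivw(h)[0].beta == pytest.approx(ivw(h2)[0].beta, rel=1e-12)
    assert mr_egger(h)[0].beta == pytest.approx(mr_egger(h2)[0].beta, rel=1e-12)
    assert weighted_median(h, 50, 0).beta == pytest.approx(
        weighted_median(h2, 50, 0).beta, rel=1e-12
    )


# ------------------------------------------------------------ diagnostics


def test_q_statistic_calibration_under_null():
    """Q ~ chi-square(n-1) for homogeneous data: 5% rejection within band."""
    rng = np.random.default_rng(21)
    n_rep, n_snp = 2000, 20
    bx = rng.uniform(0.02, 0.08, n_snp)
    sy = np.full(n_snp, 0.006)
    by = 0.3 * bx + rng.normal(0, 0.006, (n_rep, n_snp))
    w = sy**-2
    beta = (w * bx * by).sum(axis=1) / (w * bx**2).sum()
    q = (w * (by - beta[:, None] * bx) ** 2).sum(axis=1)
    rate = np.mean(stats.chi2.sf(q, n_snp - 1) < 0.05)
    assert 0.03 <= rate <= 0.07


def test_leave_one_out_rows_and_outlier_ranking():
    rng = np.random.default_rng(31)
    n = 20
    bx = rng.uniform(0.02, 0.08, n)
    sy = np.full(n, 0.006)
    by = 0.3 * bx + rng.normal(0, sy)
    by[7] += 10 * 0.006  # planted outlier
    h = make_harmonized(bx, by, sy)
    loo = leave_one_out(h)
    assert len(loo) == n
    full, _ = ivw(h)
    shifts = (loo["beta"] - full.beta).abs()
    assert shifts.idxmax() == 7


def test_leave_one_out_stable_on_homogeneous_data():
    rng = np.random.default_rng(32)
    bx = rng.uniform(0.02, 0.08, 25)
    h = make_harmonized(bx, 0.3 * bx + rng.normal(0, 0.006, 25), np.full(25, 0.006))
    loo = leave_one_out(h)
    full, _ = ivw(h)
    assert np.allclose(loo["beta"], full.beta, atol=4 * full.se)
    assert not loo["flagged"].any()


def test_funnel_data_symmetry_and_domain():
    rng = np.random.default_rng(41)
    n = 2000
    bx = rng.uniform(0.04, 0.08, n)
    sy = np.full(n, 0.006)
    h = make_harmonized(bx, 0.3 * bx + rng.normal(0, sy), sy)
    fd = funnel_data(h)
    assert abs(stats.skew(fd["wald"])) < 0.15
    h1 = make_harmonized([0.05, 0.0], [0.02, 0.01], [0.01, 0.01])
    assert len(funnel_data(h1)) == 1
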