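"""Estimator battery: exact identities, oracles, and robustness behaviour."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrmediate import calibration as cal
from mrmediate.uvmr import (BatterySettings, EstimationError, MRInput, bwmr,
                            contamination_mixture, debiased_ivw, egger, ivw,
                            ivw_penalized, ivw_robust, max_likelihood,
                            run_battery)

from conftest import make_mr_input


# ---------------------------------------------------------------- IVW core

def test_single_snp_ratio():
    est = ivw(make_mr_input([0.2], [0.1], [0.05]), "fixed")
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.25)


def test_identical_ratios_give_exact_estimate_and_zero_q():
    bx = np.array([0.1, 0.2, 0.3])
    est = ivw(make_mr_input(bx, 0.3 * bx, [0.05, 0.04, 0.06]))
    assert est.beta == pytest.approx(0.3)
    assert est.q_stat == pytest.approx(0.0, abs=1e-20)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ivw_equals_wls_oracle(seed):
    """Fixed-effects IVW must equal no-intercept WLS to 1e-10."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 40))
    bx = rng.normal(0, 0.3, k)
    bx[np.abs(bx) < 1e-3] = 0.05
    by = rng.normal(0, 0.3, k)
    sy = rng.uniform(0.005, 0.5, k)
    mine = ivw(make_mr_input(bx, by, sy), "fixed").beta
    oracle = sm.WLS(by, bx, weights=1.0 / sy ** 2).fit().params[0]
    assert mine == pytest.approx(oracle, abs=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.floats(min_value=0.1, max_value=10.0))
def test_estimators_equivariant_under_exposure_rescaling(seed, c):
    rng = np.random.default_rng(seed)
    k = 12
    bx = rng.uniform(0.05, 0.3, k)
    by = 0.4 * bx + rng.normal(0, 0.02, k)
    sy = np.full(k, 0.02)
    sx = np.full(k, 0.005)
    base = make_mr_input(bx, by, sy, sx=sx)
    scaled = make_mr_input(c * bx, by, sy, sx=c * sx)
    for fn in (lambda d: ivw(d), lambda d: max_likelihood(d),
               lambda d: debiased_ivw(d)):
        assert fn(scaled).beta * c == pytest.approx(fn(base).beta, rel=1e-6)


def test_ivw_excludes_zero_exposure_effects():
    est = ivw(make_mr_input([0.0, 0.2], [0.1, 0.1], [0.05, 0.05]), "fixed")
    assert est.n_snp == 1
    with pytest.raises(EstimationError):
        ivw(make_mr_input([0.0, 0.0], [0.1, 0.1], [0.05, 0.05]))


def test_ivw_type_one_error_under_global_null():
    res = cal.ivw_null_size(n_reps=500, seed=17)
    assert 0.03 <= res["type1"] <= 0.07


# ------------------------------------------------------- robust / penalized

def test_robust_equals_fixed_ivw_on_exact_fit_data():
    bx = np.array([0.1, 0.15, 0.2, 0.25])
    data = make_mr_input(bx, 0.3 * bx, np.full(4, 0.05))
    assert ivw_robust(data).beta == pytest.approx(ivw(data, "fixed").beta)


def test_robust_resists_planted_outlier():
    rng = np.random.default_rng(3)
    k = 20
    bx = rng.uniform(0.05, 0.2, k)
    sy = np.full(k, 0.01)
    by = 0.3 * bx + rng.normal(0, 0.01, k)
    by[0] = 5.0 * bx[0]
    data = make_mr_input(bx, by, sy)
    plain = ivw(data).beta
    robust = ivw_robust(data).beta
    assert abs(robust - 0.3) < abs(plain - 0.3)


def test_robust_requires_three_instruments():
    with pytest.raises(EstimationError):
        ivw_robust(make_mr_input([0.1, 0.2], [0.05, 0.1], [0.05, 0.05]))


def test_penalization_is_inactive_on_homogeneous_ratios():
    bx = np.array([0.1, 0.15, 0.2, 0.12])
    data = make_mr_input(bx, 0.3 * bx, np.full(4, 0.05))
    assert ivw_penalized(data).beta == pytest.approx(ivw(data).beta)


def test_penalization_downweights_extreme_outlier():
    rng = np.random.default_rng(5)
    k = 15
    bx = rng.uniform(0.05, 0.2, k)
    sy = np.full(k, 0.01)
    by = 0.3 * bx + rng.normal(0, 0.01, k)
    by[0] = 4.0 * bx[0]
    data = make_mr_input(bx, by, sy)
    pen = ivw_penalized(data).beta
    plain = ivw(data).beta
    assert abs(pen - 0.3) < abs(plain - 0.3)


def test_penalized_beats_plain_ivw_across_replicates():
    """With one planted outlier the penalized fit should usually win."""
    wins = 0
    n_reps = 200
    for s in cal.rep_seeds(21, n_reps):
        rng = np.random.default_rng(int(s))
        k = 20
        bx = rng.uniform(0.05, 0.2, k)
        sy = np.full(k, 0.01)
        by = 0.3 * bx + rng.normal(0, sy)
        by[0] += 10 * sy[0] * rng.choice([-1, 1])
        data = make_mr_input(bx, by, sy)
        wins += (abs(ivw_penalized(data).beta - 0.3)
                 <= abs(ivw(data).beta - 0.3))
    assert wins / n_reps >= 0.8


# ----------------------------------------------------------------- Egger

def test_egger_intercept_null_when_no_pleiotropy(strong_mr_input):
    _, intercept = egger(strong_mr_input, "plain")
    assert abs(intercept["egger_intercept"]) \
        < 3 * intercept["intercept_se"]


def test_egger_recovers_constructed_intercept():
    res = cal.egger_directional_recovery(seed=0)
    assert abs(res["z_from_truth"]) < 3
    assert res["slope_error"] < res["ivw_error"]


def test_egger_needs_three_snps_and_noncollinear_exposure():
    with pytest.raises(EstimationError):
        egger(make_mr_input([0.1, 0.2], [0.05, 0.1], [0.05, 0.05]))
    with pytest.raises(EstimationError):
        egger(make_mr_input([0.1, 0.1, -0.1], [0.05, 0.04, 0.03],
                            [0.05, 0.05, 0.05]))


def test_egger_variants_all_run(strong_mr_input):
    results = {v: egger(strong_mr_input, v)
               for v in ("plain", "penalized", "robust", "penalized_robust")}
    for est, intercept in results.values():
        assert est.ci_low <= est.beta <= est.ci_high
        assert 0.0 < intercept["intercept_pval"] <= 1.0


# --------------------------------------------- likelihood-based estimators

def test_max_likelihood_reduces_to_ivw_without_exposure_noise():
    rng = np.random.default_rng(8)
    bx = rng.uniform(0.05, 0.3, 15)
    by = 0.25 * bx + rng.normal(0, 0.02, 15)
    data = make_mr_input(bx, by, np.full(15, 0.02))
    assert max_likelihood(data).beta == pytest.approx(
        ivw(data, "fixed").beta, abs=1e-6)


def test_max_likelihood_exact_fit():
    bx = np.array([0.1, 0.2, 0.3])
    data = make_mr_input(bx, 0.4 * bx, np.full(3, 1e-6), sx=np.full(3, 1e-6))
    assert max_likelihood(data).beta == pytest.approx(0.4, abs=1e-4)


def test_max_likelihood_less_biased_than_ivw_with_noisy_exposure():
    """Exposure measurement error dilutes IVW; the likelihood accounts for it."""
    err_ml, err_ivw = [], []
    for s in cal.rep_seeds(31, 200):
        rng = np.random.default_rng(int(s))
        k = 30
        gamma = rng.uniform(0.05, 0.2, k)
        sx = np.full(k, 0.05)
        sy = np.full(k, 0.02)
        bx = gamma + rng.normal(0, sx)
        by = 0.3 * gamma + rng.normal(0, sy)
        data = make_mr_input(bx, by, sy, sx=sx)
        err_ml.append(max_likelihood(data).beta - 0.3)
        err_ivw.append(ivw(data).beta - 0.3)
    assert abs(np.mean(err_ml)) < abs(np.mean(err_ivw))


def test_debiased_ivw_identities():
    rng = np.random.default_rng(9)
    bx = rng.uniform(0.05, 0.3, 10)
    by = 0.2 * bx + rng.normal(0, 0.02, 10)
    sy = np.full(10, 0.02)
    no_noise = make_mr_input(bx, by, sy)  # sx = 0
    assert debiased_ivw(no_noise).beta == pytest.approx(
        ivw(no_noise, "fixed").beta)
    strong = make_mr_input([0.5], [0.15], [0.01], sx=[1e-4])
    assert debiased_ivw(strong).beta == pytest.approx(0.3, rel=1e-3)


def test_debiased_ivw_less_biased_under_weak_instruments():
    err_d, err_i = [], []
    for s in cal.rep_seeds(41, 300):
        rng = np.random.default_rng(int(s))
        k = 100
        gamma = rng.normal(0, 0.02, k)
        sx = np.full(k, 0.02)
        sy = np.full(k, 0.02)
        bx = gamma + rng.normal(0, sx)
        by = 0.3 * gamma + rng.normal(0, sy)
        data = make_mr_input(bx, by, sy, sx=sx)
        try:
            err_d.append(debiased_ivw(data).beta - 0.3)
        except EstimationError:
            continue
        err_i.append(ivw(data).beta - 0.3)
    assert abs(np.mean(err_d)) < abs(np.mean(err_i))


# ------------------------------------------------- contamination mixture

def test_contamination_mixture_on_clean_tight_ratios():
    bx = np.linspace(0.1, 0.3, 10)
    data = make_mr_input(bx, 0.3 * bx, np.full(10, 0.005))
    est = contamination_mixture(data)
    assert est.beta == pytest.approx(0.3, abs=0.02)
    assert est.ci_low <= est.beta <= est.ci_high


def test_contamination_mixture_finds_largest_coherent_subset():
    rng = np.random.default_rng(12)
    k = 20
    bx = rng.uniform(0.1, 0.3, k)
    sy = np.full(k, 0.004)
    sy[10:] = 0.2  # contaminants carry much larger outcome SEs
    by = 0.3 * bx + rng.normal(0, 0.004, k)
    by[10:] = 2.0 * bx[10:] + rng.normal(0, 0.2, 10)
    data = make_mr_input(bx, by, sy)
    est = contamination_mixture(data, psi=0.5)
    assert est.beta == pytest.approx(0.3, abs=0.05)
    # brute-force profile likelihood over the same grid agrees
    grid = np.linspace(-3 * np.max(np.abs(by / bx)),
                       3 * np.max(np.abs(by / bx)), 500)
    r, se_r = by / bx, sy / np.abs(bx)
    from scipy import stats as sps
    ll = np.array([
        np.sum(np.maximum(sps.norm.logpdf(r, t, se_r),
                          sps.norm.logpdf(r, 0.0, np.sqrt(se_r**2 + 0.25))))
        for t in grid])
    assert est.beta == pytest.approx(grid[np.argmax(ll)], abs=1e-9)


def test_contamination_mixture_empty_grid_rejected(strong_mr_input):
    with pytest.raises(ValueError):
        contamination_mixture(strong_mr_input, grid=np.array([]))


# ----------------------------------------------------------------- BWMR

def test_bwmr_agrees_with_ivw_on_clean_data(strong_mr_input):
    b = bwmr(strong_mr_input)
    i = ivw(strong_mr_input)
    assert abs(b.beta - i.beta) < 3 * i.se


def test_bwmr_elbo_monotone_and_outlier_downweighted():
    rng = np.random.default_rng(14)
    k = 20
    bx = rng.uniform(0.05, 0.2, k)
    sx = np.full(k, 0.005)
    sy = np.full(k, 0.01)
    by = 0.3 * bx + rng.normal(0, sy)
    by[7] = 4.0 * bx[7]
    data = make_mr_input(bx, by, sy, sx=sx)
    est = bwmr(data)
    elbo = np.array(est.extra["elbo"])
    assert np.all(np.diff(elbo) > -1e-8)
    weights = est.extra["weights"]
    assert min(weights, key=weights.get) == "v7"


# --------------------------------------------------------------- battery

def test_battery_positive_scenario_sign_consistent(strong_mr_input):
    result = run_battery(strong_mr_input, BatterySettings(seed=1))
    ivw_family = [e for e in result.estimates if "IVW" in e.method]
    assert len(ivw_family) >= 4
    assert all(e.pval < 0.05 for e in ivw_family)
    assert all(np.sign(e.beta) == np.sign(ivw_family[0].beta)
               for e in ivw_family)
    assert result.presso is not None
    row = result.pval_row()
    assert "MR-PRESSO global" in row and "Egger intercept (plain)" in row


def test_battery_survives_method_failures():
    data = make_mr_input([0.1, 0.2], [0.03, 0.06], [0.02, 0.02])
    result = run_battery(data, BatterySettings(run_presso=True))
    assert result.get("IVW (fixed effects)") is not None
    assert any("Egger" in name for name in result.failures)
    assert "MR-PRESSO" in result.failures


def test_or_is_exponentiated_beta(strong_mr_input):
    est = ivw(strong_mr_input)
    assert est.or_value == pytest.approx(np.exp(est.beta))
    lo, hi = est.or_ci
    assert lo == pytest.approx(np.exp(est.ci_low))
    assert hi == pytest.approx(np.exp(est.ci_high))
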