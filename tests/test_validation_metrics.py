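"""Discrimination/calibration estimators against oracles and closed forms."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from cakival.validation_metrics import (
    SingleClassError,
    auroc,
    bootstrap_metrics,
    brier,
    calibration_curve,
    calibration_slope,
    citl,
    compare_auroc,
)


def brute_force_auroc(x, y):
    """O(n^2) pairwise-concordance oracle (ties credited 0.5)."""
    x = np.asarray(x, float)
    pos = x[np.asarray(y) == 1]
    neg = x[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


# --- AUROC ------------------------------------------------------------------

def test_auroc_hand_example():
    # events {0.9, 0.4}, non-events {0.5, 0.1}: 3 of 4 pairs concordant
    assert auroc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75


def test_auroc_degenerate_cases():
    assert auroc([0.3] * 10, [1, 0] * 5) == 0.5          # all ties
    assert auroc([1, 2, 3, 7, 8], [0, 0, 0, 1, 1]) == 1.0  # perfect separation
    with pytest.raises(SingleClassError):
        auroc([0.1, 0.2], [1, 1])


@pytest.mark.parametrize("n,tie_grid", [(20, None), (173, None), (500, 8)])
def test_auroc_matches_pairwise_oracle(n, tie_grid):
    """Rank AUROC equals the brute-force concordance oracle exactly."""
    rng = np.random.default_rng(n)
    x = rng.random(n)
    if tie_grid:
        x = np.round(x * tie_grid) / tie_grid  # force heavy ties
    y = (rng.random(n) < 0.3).astype(int)
    y[:2] = [0, 1]  # guarantee both classes
    assert auroc(x, y) == pytest.approx(brute_force_auroc(x, y), abs=1e-14)
    assert auroc(x, y) == pytest.approx(roc_auc_score(y, x), abs=1e-12)


def test_auroc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(5)
    score = rng.choice(np.arange(0, 23, 0.5), size=400)
    y = (rng.random(400) < expit(-3 + 0.2 * score)).astype(int)
    base = auroc(score, y)
    for transform in (lambda s: 3 * s - 7, lambda s: expit(0.8 * s - 4),
                      lambda s: np.expm1(s / 10)):
        assert abs(auroc(transform(score), y) - base) < 1e-12


# --- Brier ------------------------------------------------------------------

def test_brier_hand_values():
    assert brier([1.0, 0.0], [1, 0]) == 0.0
    assert brier([0.2, 0.8], [0, 1]) == pytest.approx(0.04, abs=1e-15)


def test_brier_constant_predictor_converges_to_bernoulli_variance():
    rng = np.random.default_rng(7)
    pi = 0.11
    y = (rng.random(200_000) < pi).astype(float)
    b = brier(np.full_like(y, pi), y)
    assert b == pytest.approx(pi * (1 - pi), abs=0.002)


# --- CITL -------------------------------------------------------------------

def test_citl_zero_when_probability_equals_event_rate():
    """With constant p-hat equal to the event rate the offset-logistic MLE
    intercept is exactly 0 (score equation balances)."""
    y = np.array([1] * 11 + [0] * 89, dtype=float)
    assert citl(np.full(100, 0.11), y) == pytest.approx(0.0, abs=1e-9)


def test_citl_closed_form_logit_shift():
    """Doubling the odds of calibrated predictions drives the intercept to
    -log 2 at large n."""
    rng = np.random.default_rng(21)
    n = 200_000
    p = expit(rng.normal(-2.0, 1.0, n))
    y = (rng.random(n) < p).astype(float)
    assert citl(p, y) == pytest.approx(0.0, abs=0.03)
    shifted = expit(logit(p) + np.log(2))
    assert citl(shifted, y) == pytest.approx(-np.log(2), abs=0.03)


def test_citl_sign_convention_overestimation_negative():
    rng = np.random.default_rng(3)
    n = 50_000
    p = expit(rng.normal(-2.0, 1.0, n))
    y = (rng.random(n) < p).astype(float)
    assert citl(np.clip(p * 2.5, 0, 0.99), y) < 0  # inflated predictions


# --- calibration slope ------------------------------------------------------

def test_slope_self_calibration():
    rng = np.random.default_rng(13)
    n = 100_000
    p = expit(rng.normal(-2.0, 1.2, n))
    y = (rng.random(n) < p).astype(float)
    assert calibration_slope(p, y) == pytest.approx(1.0, abs=0.05)


def test_slope_reciprocal_of_logit_exaggeration():
    rng = np.random.default_rng(17)
    n = 200_000
    lp = rng.normal(-2.0, 1.0, n)
    y = (rng.random(n) < expit(lp)).astype(float)
    exaggerated = expit(2.0 * lp)
    assert calibration_slope(exaggerated, y) == pytest.approx(0.5, abs=0.03)


def test_slope_rejects_constant_predictions():
    with pytest.raises(ValueError):
        calibration_slope([0.3] * 50, [0, 1] * 25)


def test_citl_and_slope_match_statsmodels():
    """Cross-check the in-package Newton solver against statsmodels GLM."""
    rng = np.random.default_rng(29)
    n = 3000
    p = np.clip(expit(rng.normal(-1.5, 1.0, n)) * 1.4, 1e-6, 1 - 1e-6)
    y = (rng.random(n) < 0.2).astype(float)
    lp = logit(p)
    sm_citl = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial(),
                     offset=lp).fit()
    assert citl(p, y) == pytest.approx(sm_citl.params[0], abs=1e-6)
    sm_slope = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    assert calibration_slope(p, y) == pytest.approx(sm_slope.params[1], abs=1e-6)


# --- bootstrap --------------------------------------------------------------

def _calibrated_cohort(rng, n=600, base=-2.4, sd=0.9):
    p = expit(rng.normal(base, sd, n))
    y = (rng.random(n) < p).astype(float)
    if y.sum() < 2:
        y[:2] = 1.0
    return p, y


def test_bootstrap_seed_determinism():
    rng = np.random.default_rng(31)
    p, y = _calibrated_cohort(rng, n=400)
    a = bootstrap_metrics(p, y, n_boot=50, seed=9)
    b = bootstrap_metrics(p, y, n_boot=50, seed=9)
    assert a == b
    c = bootstrap_metrics(p, y, n_boot=50, seed=10)
    assert c["auroc"].point != a["auroc"].point


def test_bootstrap_perfect_predictor_degenerate_ci():
    y = np.array([0] * 50 + [1] * 10, dtype=float)
    p = y * 0.98 + 0.01
    est = bootstrap_metrics(p, y, n_boot=100, seed=0)
    assert est["auroc"].point == 1.0
    assert est["auroc"].ci_low == est["auroc"].ci_high == 1.0


def test_bootstrap_refuses_too_few_events():
    with pytest.raises(ValueError):
        bootstrap_metrics([0.1, 0.2, 0.3, 0.4], [1, 0, 0, 0], n_boot=10, seed=0)


def test_bootstrap_slope_ci_coverage():
    """On calibrated cohorts the percentile slope CI covers 1 at close to the
    nominal 95% rate (200 generator seeds, scaled-down bootstrap)."""
    covered = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        p, y = _calibrated_cohort(rng, n=600)
        est = bootstrap_metrics(p, y, n_boot=200, seed=seed)["slope"]
        covered += est.ci_low <= 1.0 <= est.ci_high
    assert 0.89 <= covered / n_seeds <= 0.995


# --- AUROC comparison -------------------------------------------------------

def test_compare_auroc_identical_models():
    rng = np.random.default_rng(37)
    p, y = _calibrated_cohort(rng, n=300)
    res = compare_auroc(p, p, y, n_boot=200, seed=1)
    assert res.delta == 0.0
    assert res.p_value == 1.0


def test_compare_auroc_maximal_separation_hits_floor():
    y = np.array([0] * 400 + [1] * 100, dtype=float)
    perfect = y.copy()
    constant = np.full_like(y, 0.5)
    res = compare_auroc(perfect, constant, y, n_boot=200, seed=2)
    assert res.p_value == pytest.approx(1 / 200)
    assert res.ci_low > 0


def test_compare_auroc_null_type_i_error():
    """Two independent noisy copies of one signal: the test rejects at ~alpha
    under the null."""
    rejections = 0
    n_sims = 500
    rng = np.random.default_rng(41)
    for _ in range(n_sims):
        n = 300
        signal = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(-1.5 + 0.8 * signal)).astype(float)
        if y.sum() < 2 or y.sum() > n - 2:
            continue
        a = signal + rng.normal(0, 1, n)
        b = signal + rng.normal(0, 1, n)
        res = compare_auroc(a, b, y, n_boot=100, seed=int(rng.integers(2**31)))
        rejections += res.p_value < 0.05
    # binomial 99.9% envelope around 0.05 at ~500 sims
    assert 0.01 <= rejections / n_sims <= 0.10


# --- calibration curve ------------------------------------------------------

def test_calibration_curve_conservation():
    rng = np.random.default_rng(43)
    p, y = _calibrated_cohort(rng, n=1000)
    curve = calibration_curve(p, y, n_bins=10)
    assert curve.bins["n"].sum() == 1000
    assert curve.bins["events"].sum() == int(y.sum())
    assert len(curve.bins) == 10
    assert curve.bins["mean_predicted"].is_monotonic_increasing


def test_calibration_curve_near_diagonal_when_calibrated():
    rng = np.random.default_rng(47)
    p, y = _calibrated_cohort(rng, n=50_000)
    curve = calibration_curve(p, y, n_bins=10)
    resid = curve.bins["observed_rate"] - curve.bins["mean_predicted"]
    assert np.all(np.abs(resid) < 0.03)


def test_calibration_curve_degenerate_predictions_merge():
    y = np.array([0, 1] * 30, dtype=float)
    p = np.full(60, 0.5)
    with pytest.warns(RuntimeWarning):
        curve = calibration_curve(p, y, n_bins=10)
    assert len(curve.bins) == 1
    assert curve.bins.loc[0, "observed_rate"] == 0.5
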