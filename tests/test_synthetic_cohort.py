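"""Synthetic cohort generator: frozen defaults, determinism, class-consistent
trajectories and marginal/prevalence recovery."""

import dataclasses

import numpy as np
import pytest

from cakival._glm import fit_logistic
from cakival.outcome_labeling import label_outcomes
from cakival.pipeline import label_cohort
from cakival.synthetic_cohort import (
    CohortConfig,
    CohortConfigError,
    OutcomeParams,
    apply_missingness,
    default_config,
    egfr_jsn,
    generate_cohort,
    lognormal_sigma_from_iqr,
    records_from_csv,
    records_to_csv,
)


def test_default_config_frozen_and_idempotent():
    a = default_config()
    b = default_config()
    assert a == b
    assert a.n_patients == 1684
    assert a.missingness_rates["magnesium"] == 0.612
    assert a.missingness_rates["albumin"] == 0.060
    assert a.covariate_params["cddp_dose"]["median"] == 110.0
    assert a.outcome_params.caki_prevalence == 0.110
    assert a.outcome_params.severe_prevalence == 0.021


@pytest.mark.parametrize(
    "patch, field",
    [
        ({"n_patients": 0}, "n_patients"),
        ({"rrt_rate_given_severe": 1.5}, "rrt_rate_given_severe"),
        ({"missingness_rates": {"magnesium": 1.2}}, "magnesium"),
        ({"missingness_rates": {"bogus_lab": 0.1}}, "bogus_lab"),
        ({"outcome_params": OutcomeParams(caki_prevalence=-0.1)}, "caki_prevalence"),
        ({"outcome_params": OutcomeParams(caki_prevalence=0.01,
                                          severe_prevalence=0.5)}, "severe_prevalence"),
    ],
)
def test_invalid_config_names_offending_field(patch, field):
    cfg = dataclasses.replace(default_config(), **patch)
    with pytest.raises(CohortConfigError, match=field):
        cfg.validate()


def test_seed_determinism_byte_identical_csv(default_cfg):
    cfg = dataclasses.replace(default_cfg, n_patients=300, seed=5)
    recs1, truth1 = generate_cohort(cfg)
    recs2, truth2 = generate_cohort(cfg)
    assert records_to_csv(recs1) == records_to_csv(recs2)
    assert truth1.equals(truth2)
    # different seed changes the cohort
    recs3, _ = generate_cohort(dataclasses.replace(cfg, seed=6))
    assert records_to_csv(recs3) != records_to_csv(recs1)


def test_label_round_trip_reproduces_truth(default_cohort):
    """Outcome labelling applied to the synthesized trajectories reproduces
    the sampled truth class for every patient."""
    records, truth = default_cohort
    labels = label_cohort(records)
    assert (labels["caki"].to_numpy() == truth["true_caki"].to_numpy()).all()
    assert (labels["severe_caki"].to_numpy() == truth["true_severe"].to_numpy()).all()
    assert set(truth["true_class"]) == {"none", "stage1", "severe"}


def test_degenerate_prevalence_zero(default_cfg):
    cfg = dataclasses.replace(
        default_cfg, n_patients=400, seed=3,
        outcome_params=dataclasses.replace(
            default_cfg.outcome_params, caki_prevalence=0.0, severe_prevalence=0.0),
    )
    records, truth = generate_cohort(cfg)
    assert not truth["true_caki"].any()
    for r in records:
        lab = label_outcomes(r)
        assert not lab.caki and not r.rrt_within_window


def test_degenerate_prevalence_one_forces_severe_trajectories(default_cfg):
    cfg = dataclasses.replace(
        default_cfg, n_patients=300, seed=4, rrt_rate_given_severe=0.0,
        outcome_params=dataclasses.replace(
            default_cfg.outcome_params, caki_prevalence=1.0, severe_prevalence=1.0),
    )
    records, truth = generate_cohort(cfg)
    assert truth["true_severe"].all()
    for r in records:
        peak = max(v for _d, v in r.creatinine_series)
        assert peak / r.baseline_creatinine >= 2.0


def test_marginal_recovery_at_large_n(big_cohort):
    """Sample median/IQR of each continuous covariate within 3% of targets."""
    records, _ = big_cohort
    cfg = default_config()
    cols = {
        "age": np.array([r.age for r in records]),
        "cddp_dose": np.array([r.cddp_dose for r in records]),
        "baseline_creatinine": np.array([r.baseline_creatinine for r in records]),
        "albumin": np.array([r.albumin for r in records]),
        "hemoglobin": np.array([r.hemoglobin for r in records]),
        "wbc": np.array([r.wbc for r in records]),
        "platelets": np.array([r.platelets for r in records]),
        "magnesium": np.array([r.magnesium for r in records]),
    }
    targets = {
        "age": (66, 58, 71),
        "cddp_dose": (110, 90, 130),
        "baseline_creatinine": (0.75, 0.63, 0.87),
        "albumin": (3.9, 3.5, 4.2),
        "hemoglobin": (12.5, 11.3, 13.6),
        "wbc": (5.99, 4.64, 7.56),
        "platelets": (256, 203, 313),
        "magnesium": (2.05, 2.00, 2.10),
    }
    for name, (med, q25, q75) in targets.items():
        got = np.percentile(cols[name], [50, 25, 75])
        for target, sample in zip((med, q25, q75), got):
            assert abs(sample - target) / target < 0.03, (name, target, sample)
    # binary covariate rates (3 binomial SEs at n = 50,000)
    htn = np.mean([r.hypertension for r in records])
    assert abs(htn - 0.353) < 3 * np.sqrt(0.353 * 0.647 / len(records))
    male = np.mean([r.sex == "male" for r in records])
    assert abs(male - 0.667) < 3 * np.sqrt(0.667 * 0.333 / len(records))


def test_prevalence_recovery_at_large_n(big_cohort):
    records, truth = big_cohort
    n = len(records)
    labels = label_cohort(records)
    for col, target in (("caki", 0.110), ("severe_caki", 0.021)):
        rate = labels[col].mean()
        se = np.sqrt(target * (1 - target) / n)
        assert abs(rate - target) < 3 * se, (col, rate)


def test_outcome_weight_recovery(big_cohort):
    """Logistic refit of the sampled C-AKI outcome on the noiseless scores
    recovers the configured per-point log-odds weights."""
    _records, truth = big_cohort
    op = default_config().outcome_params
    X = np.column_stack([
        np.ones(len(truth)),
        truth["gupta_score_true"].to_numpy(),
        truth["motwani_score_true"].to_numpy(),
    ])
    beta = fit_logistic(X, truth["true_caki"].to_numpy(dtype=float))
    assert beta[1] == pytest.approx(op.caki_weight_gupta, abs=0.03)
    assert beta[2] == pytest.approx(op.caki_weight_motwani, abs=0.03)


def test_age_hypertension_association(big_cohort):
    records, _ = big_cohort
    age = np.array([r.age for r in records])
    htn = np.array([r.hypertension for r in records])
    assert age.min() >= 18
    assert htn[age > 70].mean() > htn[age < 60].mean()


def test_missingness_rates_and_masks(default_cfg):
    cfg = dataclasses.replace(default_cfg, n_patients=10_000, seed=8)
    records, _ = generate_cohort(cfg)
    masked, mask_df = apply_missingness(records, cfg)
    mg_frac = np.mean([r.magnesium is None for r in masked])
    assert 0.60 <= mg_frac <= 0.625  # binomial 99% interval at n = 10,000
    assert (mask_df["magnesium"].mean()) == pytest.approx(mg_frac)
    # non-lab fields untouched
    assert all(a.age == b.age for a, b in zip(records, masked))


def test_missingness_degenerate_rates(default_cfg):
    cfg = dataclasses.replace(default_cfg, n_patients=50, seed=9)
    records, _ = generate_cohort(cfg)
    zero = dataclasses.replace(cfg, missingness_rates={})
    same, _ = apply_missingness(records, zero)
    assert same == records
    full = dataclasses.replace(cfg, missingness_rates={"magnesium": 1.0})
    gone, _ = apply_missingness(records, full)
    assert all(r.magnesium is None for r in gone)


def test_mar_mode_masks_older_patients_more(default_cfg):
    cfg = dataclasses.replace(default_cfg, n_patients=20_000, seed=10,
                              missingness_mode="mar")
    records, _ = generate_cohort(cfg)
    masked, _ = apply_missingness(records, cfg)
    age = np.array([r.age for r in records])
    miss = np.array([r.magnesium is None for r in masked])
    assert miss[age > 70].mean() > miss[age < 60].mean()
    # marginal rate still matches the configured target
    assert abs(miss.mean() - 0.612) < 0.02


def test_cohort_csv_round_trip(default_cfg):
    cfg = dataclasses.replace(default_cfg, n_patients=120, seed=12)
    records, _ = generate_cohort(cfg)
    masked, _ = apply_missingness(records, cfg)
    text = records_to_csv(masked)
    back = records_from_csv(text)
    assert back == masked


def test_lognormal_sigma_helper():
    # symmetric-on-log IQR reproduces the quartile ratio
    sigma = lognormal_sigma_from_iqr(90.0, 130.0)
    assert np.exp(2 * 0.6744897501960817 * sigma) == pytest.approx(130 / 90)
    with pytest.raises(ValueError):
        lognormal_sigma_from_iqr(2.0, 1.0)


def test_egfr_japanese_equation_properties():
    male = egfr_jsn(0.75, 66, "male")
    female = egfr_jsn(0.75, 66, "female")
    assert female == pytest.approx(0.739 * male)
    assert egfr_jsn(1.5, 66, "male") < male       # worse with higher creatinine
    assert egfr_jsn(0.75, 80, "male") < male      # worse with age
    assert 50 < male < 110                        # plausible range for the cohort median
    with pytest.raises(ValueError):
        egfr_jsn(0.75, 66, "other")
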