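"""Through-origin mixed models: oracles, invariances, joint model."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import wmh_atrophy as wa
from conftest import deterministic_group
from wmh_atrophy.longitudinal import joint_loglik_at, loglik_at


def _cohort(group, seed, **cfg_kw):
    return wa.generate_cohort(wa.CohortConfig(groups=[group], seed=seed, **cfg_kw))


# --- univariate fit ---------------------------------------------------------

def test_noise_free_fit_is_exact():
    """All subjects share rate 0.07 with zero noise: the mean-rate
    estimate is exact and both variance components collapse to zero."""
    c = _cohort(deterministic_group(), seed=1, interval_jitter_yr=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = wa.build_design(c.subjects, c.observations, "hippo", covariates=())
        fit = wa.fit_rate_lmm(d)
    assert fit.coef("rate") == pytest.approx(0.07, abs=1e-9)
    assert fit.sigma_b < 1e-8 and fit.sigma_e < 1e-8


def test_zero_slope_variance_reduces_to_ols():
    """When no between-subject heterogeneity was generated, the GLS fit
    collapses onto direct through-origin least squares."""
    g = dataclasses.replace(wa.control_params(n=150),
                            slope_sd_brain=0.0, slope_sd_hippo=0.0)
    c = _cohort(g, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = wa.build_design(c.subjects, c.observations, "hippo")
        fit = wa.fit_rate_lmm(d)
    X = d.u[d.obs_subject] * d.t[:, None]
    ols = np.linalg.lstsq(X, d.y, rcond=None)[0]
    np.testing.assert_allclose(fit.beta, ols, rtol=1e-6)


def test_matches_reference_mixed_model_implementation(control_fits):
    """Estimates agree with an established mixed-model fitter (ML) to
    1e-4 relative tolerance on a shared cohort."""
    import statsmodels.api as sm

    for outcome in ("hippo", "brain"):
        d = control_fits[f"design_{outcome}"]
        fit = control_fits[outcome]
        X = pd.DataFrame(d.u[d.obs_subject] * d.t[:, None], columns=d.names)
        md = sm.MixedLM(d.y, X, groups=d.subject_ids[d.obs_subject],
                        exog_re=X[["rate"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = md.fit(reml=False)
        np.testing.assert_allclose(fit.beta, ref.params[:len(d.names)].to_numpy(),
                                   rtol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert fit.sigma_b**2 == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                               rel=1e-3)


def test_likelihood_peaks_above_generating_parameters(control_fits):
    g = wa.control_params()
    fit = control_fits["hippo"]
    beta_gen = np.array([g.rate_hippo.alpha, g.rate_hippo.beta_wmh,
                         g.rate_hippo.beta_tiv])
    ll_gen = loglik_at(fit.design, beta_gen, g.slope_sd_hippo, g.resid_sd_hippo)
    assert fit.loglik >= ll_gen


def test_estimates_invariant_to_subject_order(control_cohort):
    c = control_cohort
    perm = np.random.default_rng(0).permutation(len(c.subjects))
    subj = c.subjects.iloc[perm].reset_index(drop=True)
    obs = c.observations.sample(frac=1.0, random_state=1).reset_index(drop=True)
    f1 = wa.fit_rate_lmm(wa.build_design(c.subjects, c.observations, "hippo"))
    f2 = wa.fit_rate_lmm(wa.build_design(subj, obs, "hippo"))
    np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-6)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)


def test_tiv_rescaling_compensates_coefficient(control_cohort):
    """Scaling TIV by a constant scales its coefficient inversely and
    leaves the other estimates unchanged."""
    c = control_cohort
    scaled = c.subjects.copy()
    scaled["tiv_ml"] = scaled["tiv_ml"] * 10.0
    f1 = wa.fit_rate_lmm(wa.build_design(c.subjects, c.observations, "hippo"))
    f2 = wa.fit_rate_lmm(wa.build_design(scaled, c.observations, "hippo"))
    assert f2.coef("tiv") == pytest.approx(f1.coef("tiv") / 10.0, rel=1e-5)
    assert f2.coef("rate") == pytest.approx(f1.coef("rate"), rel=1e-6)
    assert f2.coef("log2wmh") == pytest.approx(f1.coef("log2wmh"), rel=1e-5)


def test_rank_deficient_design_rejected(control_cohort):
    c = control_cohort
    d = wa.build_design(c.subjects, c.observations, "hippo")
    d2 = wa.LongDesign(d.subject_ids, np.c_[d.u, d.u[:, 1]],
                       d.names + ["dup"], d.obs_subject, d.t, d.y)
    with pytest.raises(ValueError, match="rank"):
        wa.fit_rate_lmm(d2)


# --- BLUPs ------------------------------------------------------------------

def test_blups_equal_fixed_prediction_when_no_heterogeneity():
    g = dataclasses.replace(wa.control_params(n=120),
                            slope_sd_brain=0.0, slope_sd_hippo=0.0)
    c = _cohort(g, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = wa.fit_rate_lmm(wa.build_design(c.subjects, c.observations, "hippo"))
    b = wa.blup_rates(fit)
    np.testing.assert_allclose(b["predicted_rate_ml_yr"],
                               b["fixed_effect_rate_ml_yr"], atol=1e-4)


def test_blups_approach_observed_rate_as_noise_vanishes():
    g = dataclasses.replace(wa.control_params(n=60), resid_sd_hippo=1e-6,
                            visit_months=(0, 12), retention=(1.0,))
    c = _cohort(g, seed=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = wa.fit_rate_lmm(wa.build_design(c.subjects, c.observations, "hippo"))
    b = wa.blup_rates(fit).set_index("subject_id")
    obs = c.observations.set_index("subject_id")
    raw_rate = obs["bsi_hippo_ml"] / obs["interval_years"]
    np.testing.assert_allclose(b.loc[raw_rate.index, "predicted_rate_ml_yr"],
                               raw_rate, atol=1e-3)


def test_blups_track_latent_rates(control_cohort, control_fits):
    b = wa.blup_rates(control_fits["hippo"]).set_index("subject_id")
    latent = control_cohort.subjects.set_index("subject_id")["latent_rate_hippo_ml_yr"]
    r = np.corrcoef(b["predicted_rate_ml_yr"], latent.loc[b.index])[0, 1]
    assert r > 0.8


# --- joint bivariate model --------------------------------------------------

def test_joint_factorizes_when_slopes_independent():
    g = dataclasses.replace(wa.control_params(n=300), slope_corr=0.0)
    c = _cohort(g, seed=5)
    dB = wa.build_design(c.subjects, c.observations, "brain")
    dH = wa.build_design(c.subjects, c.observations, "hippo")
    joint = wa.fit_joint_lmm(dB, dH)
    fB, fH = wa.fit_rate_lmm(dB), wa.fit_rate_lmm(dH)
    # the fitted correlation is near zero, so the fixed effects match the
    # two separate fits within a fraction of their SEs
    assert np.all(np.abs(joint.beta_brain - fB.beta) < 0.2 * fB.se)
    assert np.all(np.abs(joint.beta_hippo - fH.beta) < 0.2 * fH.se)
    # exact statement: with a diagonal Sigma the joint likelihood is the
    # sum of the two univariate likelihoods
    Sigma = np.diag([fB.sigma_b**2 + 1e-12, fH.sigma_b**2 + 1e-12])
    ll_joint = joint_loglik_at(joint, fB.beta, fH.beta, Sigma,
                               fB.sigma_e, fH.sigma_e)
    assert ll_joint == pytest.approx(fB.loglik + fH.loglik, abs=1e-5)


def test_joint_recovers_slope_covariance():
    g = dataclasses.replace(wa.control_params(n=3000), resid_sd_brain=0.01,
                            resid_sd_hippo=1e-4,
                            visit_months=(0, 6, 12, 18, 24, 36),
                            retention=(1.0,) * 5)
    c = _cohort(g, seed=6)
    joint = wa.fit_joint_lmm(wa.build_design(c.subjects, c.observations, "brain"),
                             wa.build_design(c.subjects, c.observations, "hippo"))
    true = g.slope_cov()
    assert np.all(np.abs(joint.Sigma - true) / np.abs(true) < 0.05)


def test_joint_handles_missing_outcome_subjects(control_cohort):
    """Subjects missing the hippocampal outcome still contribute their
    whole-brain information; the brain estimates barely move."""
    c = control_cohort
    obs = c.observations.copy()
    # delete hippocampal data for 80% of subjects
    ids = np.sort(c.subjects["subject_id"].unique())
    lost = set(ids[: int(0.8 * len(ids))])
    obs.loc[obs["subject_id"].isin(lost), "bsi_hippo_ml"] = np.nan
    dB = wa.build_design(c.subjects, obs, "brain")
    dH = wa.build_design(c.subjects, obs, "hippo")
    assert dH.n_subjects < dB.n_subjects
    joint = wa.fit_joint_lmm(dB, dH)
    fB = wa.fit_rate_lmm(dB)
    assert np.all(np.abs(joint.beta_brain - fB.beta) < 0.5 * fB.se)


def test_loglik_at_optimum_beats_generating_parameters_joint(control_cohort,
                                                             control_fits):
    g = wa.control_params()
    joint = wa.fit_joint_lmm(control_fits["design_brain"],
                             control_fits["design_hippo"])
    beta_B = np.array([g.rate_brain.alpha, g.rate_brain.beta_wmh, g.rate_brain.beta_tiv])
    beta_H = np.array([g.rate_hippo.alpha, g.rate_hippo.beta_wmh, g.rate_hippo.beta_tiv])
    ll_gen = joint_loglik_at(joint, beta_B, beta_H, g.slope_cov(),
                             g.resid_sd_brain, g.resid_sd_hippo)
    assert joint.loglik >= ll_gen


# --- adjusted association ---------------------------------------------------

def test_adjusted_equals_unadjusted_when_independent():
    g = dataclasses.replace(wa.control_params(n=400), slope_corr=0.0)
    c = _cohort(g, seed=7)
    joint = wa.fit_joint_lmm(wa.build_design(c.subjects, c.observations, "brain"),
                             wa.build_design(c.subjects, c.observations, "hippo"))
    adj = wa.adjusted_association(joint, "hippo")
    unadj = joint.coef("hippo", "log2wmh")
    # the fitted correlation is approximately (not exactly) zero
    assert adj.estimate == pytest.approx(unadj, abs=0.5 * adj.se)


def test_adjusted_matches_two_stage_oracle():
    """Large n, tiny residual noise: the conditional estimand agrees with
    per-subject through-origin OLS rates followed by OLS of the
    hippocampal rate on log2WMH + TIV + brain rate."""
    g = dataclasses.replace(wa.control_params(n=2000), resid_sd_brain=0.01,
                            resid_sd_hippo=1e-4,
                            visit_months=(0, 6, 12, 18, 24, 36),
                            retention=(1.0,) * 5)
    c = _cohort(g, seed=8)
    joint = wa.fit_joint_lmm(wa.build_design(c.subjects, c.observations, "brain"),
                             wa.build_design(c.subjects, c.observations, "hippo"))
    adj = wa.adjusted_association(joint, "hippo")

    obs = c.observations
    t = obs["interval_years"]
    parts = {}
    for o, col in (("brain", "bsi_brain_ml"), ("hippo", "bsi_hippo_ml")):
        num = (t * obs[col]).groupby(obs["subject_id"]).sum()
        den = (t**2).groupby(obs["subject_id"]).sum()
        parts[o] = num / den
    m = pd.DataFrame(parts).reset_index().merge(
        c.subjects[["subject_id", "log2wmh", "tiv_ml"]], on="subject_id")
    X = np.column_stack([np.ones(len(m)), m["log2wmh"] - m["log2wmh"].mean(),
                         m["tiv_ml"] - m["tiv_ml"].mean(), m["brain"]])
    oracle = np.linalg.lstsq(X, m["hippo"], rcond=None)[0][1]
    assert adj.estimate == pytest.approx(oracle, rel=0.10)


def test_adjusted_undefined_at_zero_variance(control_fits):
    joint = wa.fit_joint_lmm(control_fits["design_brain"],
                             control_fits["design_hippo"])
    broken = dataclasses.replace(joint, Sigma=np.zeros((2, 2)))
    with pytest.raises(ValueError, match="undefined|zero"):
        wa.adjusted_association(broken, "hippo")


# --- CSF-augmented models ---------------------------------------------------

def test_csf_null_effects_ci_coverage():
    """Zero generated CSF effects: CIs cover 0 in >= 93% of replicates."""
    g = wa.csf_control_params(n=100)
    g = dataclasses.replace(
        g, rate_hippo=dataclasses.replace(g.rate_hippo, beta_ab42=0.0, beta_tau=0.0))
    cover_ab = cover_tau = 0
    n_rep = 100
    for s in range(n_rep):
        c = _cohort(g, seed=900 + s)
        d = wa.build_design(c.subjects, c.observations, "hippo", csf=True)
        fit = wa.fit_rate_lmm(d)
        for nm, bucket in (("ab42_per10", "ab"), ("tau_per10", "tau")):
            i = fit.names.index(nm)
            hit = fit.ci_low[i] <= 0.0 <= fit.ci_high[i]
            if bucket == "ab":
                cover_ab += hit
            else:
                cover_tau += hit
    assert cover_ab >= 93 and cover_tau >= 93


def test_csf_location_shift_moves_only_mean_rate():
    """Adding a constant to every tau value leaves the tau slope (and all
    other coefficients) unchanged; only the centering-dependent mean rate
    could move, and with re-centering it does not either."""
    c = _cohort(wa.csf_control_params(n=120), seed=10)
    shifted = c.subjects.copy()
    shifted["csf_tau_pg_ml"] = shifted["csf_tau_pg_ml"] + 50.0
    f1 = wa.fit_rate_lmm(wa.build_design(c.subjects, c.observations, "hippo", csf=True))
    f2 = wa.fit_rate_lmm(wa.build_design(shifted, c.observations, "hippo", csf=True))
    assert f2.coef("tau_per10") == pytest.approx(f1.coef("tau_per10"), rel=1e-6)
    assert f2.coef("log2wmh") == pytest.approx(f1.coef("log2wmh"), rel=1e-6)
    assert f2.coef("rate") == pytest.approx(f1.coef("rate"), rel=1e-6)


def test_csf_fit_restricted_to_biomarker_subset():
    g = wa.control_params(n=200, csf_fraction=0.5)
    c = _cohort(g, seed=11)
    d = wa.build_design(c.subjects, c.observations, "hippo", csf=True)
    assert d.n_subjects == int(c.subjects["csf_available"].sum())


# --- TIV x WMH interaction and LRT ------------------------------------------

def test_identical_models_give_null_lrt(control_fits):
    lrt = wa.likelihood_ratio_test(control_fits["hippo"], control_fits["hippo"], df=0)
    assert lrt.statistic == pytest.approx(0.0, abs=1e-9)
    assert lrt.p == 1.0


def test_non_nested_models_rejected(control_fits):
    with pytest.raises(ValueError):
        wa.likelihood_ratio_test(control_fits["hippo"], control_fits["hippo"], df=-1)


def test_interaction_recovery():
    g = wa.control_params()
    g = dataclasses.replace(g, rate_brain=dataclasses.replace(g.rate_brain,
                                                              gamma_tiv_wmh=0.2))
    vals = []
    for s in range(15):
        c = _cohort(g, seed=1200 + s)
        full, reduced, lrt = wa.fit_with_tiv_wmh_interaction(
            c.subjects, c.observations, "brain")
        vals.append(full.coef("tiv_x_log2wmh_per100ml"))
        assert lrt.df == 2
        assert len(full.names) == len(reduced.names) + 2
    # MC tolerance: SE of the mean of 15 replicates is about 0.025
    assert np.mean(vals) == pytest.approx(0.2, abs=0.08)


def test_lrt_type_i_error_calibrated():
    """Under a null with no WMH effect and no interaction, the df=2 LRT
    rejects at the 5% level between 3% and 7% of the time."""
    g = wa.control_params(n=150)
    g = dataclasses.replace(g, rate_brain=dataclasses.replace(
        g.rate_brain, beta_wmh=0.0, gamma_tiv_wmh=0.0))
    n_rep = 500
    rejections = 0
    for s in range(n_rep):
        c = _cohort(g, seed=20_000 + s)
        _, _, lrt = wa.fit_with_tiv_wmh_interaction(c.subjects, c.observations,
                                                    "brain")
        rejections += lrt.p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


# --- Wald CI calibration ----------------------------------------------------

def test_wmh_ci_coverage_and_bias():
    """Over 200 control cohorts the 95% Wald CI for the hippocampal WMH
    coefficient covers the generating value 92-98% of the time, and the
    mean estimate is within 10% of it."""
    g = wa.control_params()
    true = g.rate_hippo.beta_wmh
    cover = 0
    ests = []
    n_rep = 200
    for s in range(n_rep):
        c = _cohort(g, seed=30_000 + s)
        fit = wa.fit_rate_lmm(wa.build_design(c.subjects, c.observations, "hippo"))
        i = fit.names.index("log2wmh")
        cover += fit.ci_low[i] <= true <= fit.ci_high[i]
        ests.append(fit.beta[i])
    assert 0.92 * n_rep <= cover <= 0.98 * n_rep
    assert abs(np.mean(ests) - true) < 0.10 * true
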