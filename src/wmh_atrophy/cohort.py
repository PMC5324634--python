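"""Synthetic longitudinal cohort generation.

Generates subject tables (baseline covariates, latent atrophy rates)
and scan-pair observation tables (boundary-shift-integral outcomes,
baseline anchored to each attended follow-up visit) with monotone
dropout, optionally dependent on the latent atrophy rate (missing at
random given the latent slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import VRF_NAMES, CohortConfig, GroupParams

SUBJECT_COLUMNS = [
    "subject_id", "group", "age_years", "gender", "mmse",
    "tiv_ml", "wmh_ml", "log2wmh",
    "csf_available", "csf_ab42_pg_ml", "csf_tau_pg_ml",
    *VRF_NAMES,
    "baseline_brain_ml", "baseline_hippo_ml",
    "latent_rate_brain_ml_yr", "latent_rate_hippo_ml_yr",
]

OBSERVATION_COLUMNS = ["subject_id", "visit_month", "interval_years",
                       "bsi_brain_ml", "bsi_hippo_ml"]


@dataclass
class Cohort:
    """A generated cohort: one row per subject, one row per scan pair."""

    subjects: pd.DataFrame
    observations: pd.DataFrame

    def group(self, name: str) -> "Cohort":
        subj = self.subjects[self.subjects["group"] == name].reset_index(drop=True)
        obs = self.observations[
            self.observations["subject_id"].isin(subj["subject_id"])
        ].reset_index(drop=True)
        return Cohort(subj, obs)


def _generate_group(g: GroupParams, cfg: CohortConfig, rng: np.random.Generator,
                    id_offset: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = g.n
    subject_id = np.arange(id_offset, id_offset + n)

    age = rng.normal(g.age_mean, g.age_sd, n)
    male = rng.random(n) < g.male_fraction
    mmse = np.clip(rng.normal(g.mmse_mean, g.mmse_sd, n), 0, 30).round(1)
    tiv = rng.normal(g.tiv_mean_ml, g.tiv_sd_ml, n)
    log2wmh = rng.normal(g.log2wmh_mean, g.log2wmh_sd, n)
    wmh = np.exp2(log2wmh)

    csf_avail = rng.random(n) < g.csf_fraction
    ab42 = np.clip(rng.normal(g.csf_ab42_mean, g.csf_ab42_sd, n), 40.0, None)
    tau = np.clip(rng.normal(g.csf_tau_mean, g.csf_tau_sd, n), 10.0, None)

    vrf = {nm: rng.random(n) < g.vrf_prevalence[nm] for nm in VRF_NAMES}

    # baseline volumes, centered generating model
    dt = tiv - g.tiv_mean_ml
    dw = log2wmh - g.log2wmh_mean
    bb = g.baseline_brain
    bh = g.baseline_hippo
    brain0 = (bb.intercept + bb.beta_tiv * dt + bb.beta_wmh * dw
              + bb.beta_male * male + rng.normal(0.0, bb.resid_sd, n))
    hippo0 = (bh.intercept + bh.beta_tiv * dt + bh.beta_wmh * dw
              + bh.beta_male * male + rng.normal(0.0, bh.resid_sd, n))
    # anatomical ordering guard (essentially never binds at calibrated SDs)
    hippo0 = np.clip(hippo0, 0.5, None)
    brain0 = np.clip(brain0, hippo0 + 1.0, tiv - 1.0)

    # latent atrophy rates: centered fixed part plus correlated random slopes
    # eigendecomposition handles singular covariances (zero slope SDs)
    evals, evecs = np.linalg.eigh(g.slope_cov())
    scale = evecs * np.sqrt(np.clip(evals, 0.0, None))
    slopes = rng.standard_normal((n, 2)) @ scale.T
    dab = (ab42 - g.csf_ab42_mean) / 10.0
    dtau = (tau - g.csf_tau_mean) / 10.0
    dage = age - g.age_mean
    rates = {}
    for outcome, rm, b in (("brain", g.rate_brain, slopes[:, 0]),
                           ("hippo", g.rate_hippo, slopes[:, 1])):
        mean_rate = (rm.alpha
                     + rm.beta_wmh * dw
                     + rm.beta_tiv * dt
                     + rm.gamma_tiv_wmh * (dt / 100.0) * dw
                     + rm.beta_ab42 * dab
                     + rm.beta_tau * dtau
                     + rm.beta_age * dage)
        for coef, nm in zip(rm.beta_vrf, VRF_NAMES):
            if coef:
                mean_rate = mean_rate + coef * vrf[nm]
        rates[outcome] = mean_rate + b

    subjects = pd.DataFrame({
        "subject_id": subject_id,
        "group": g.name,
        "age_years": age.round(1),
        "gender": np.where(male, "male", "female"),
        "mmse": mmse,
        "tiv_ml": tiv,
        "wmh_ml": wmh,
        "log2wmh": log2wmh,
        "csf_available": csf_avail,
        "csf_ab42_pg_ml": np.where(csf_avail, ab42, np.nan),
        "csf_tau_pg_ml": np.where(csf_avail, tau, np.nan),
        **{nm: vrf[nm] for nm in VRF_NAMES},
        "baseline_brain_ml": brain0,
        "baseline_hippo_ml": hippo0,
        "latent_rate_brain_ml_yr": rates["brain"],
        "latent_rate_hippo_ml_yr": rates["hippo"],
    })

    # visit attendance: monotone dropout, first follow-up always attended
    # when its retention probability is 1
    followups = np.asarray(g.visit_months[1:], dtype=float)
    n_fu = len(followups)
    retained = np.ones((n, n_fu), dtype=bool)
    # MAR shift: retention log-odds decrease with the latent brain slope
    if cfg.mar_strength and g.slope_sd_brain > 0:
        z = slopes[:, 0] / g.slope_sd_brain
    else:
        z = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    for j, r in enumerate(g.retention):
        if r >= 1.0:
            p = np.ones(n)
        elif r <= 0.0:
            p = np.zeros(n)
        else:
            logit = np.log(r / (1.0 - r)) - cfg.mar_strength * z
            p = 1.0 / (1.0 + np.exp(-logit))
        stay = rng.random(n) < p
        alive = alive & stay
        retained[:, j] = alive

    # intervals in years with optional uniform jitter around nominal times
    nominal = np.tile(followups / 12.0, (n, 1))
    if cfg.interval_jitter_yr > 0:
        nominal = nominal + rng.uniform(-cfg.interval_jitter_yr,
                                        cfg.interval_jitter_yr, size=nominal.shape)

    rows_subj, rows_month, rows_t = [], [], []
    for j in range(n_fu):
        idx = np.nonzero(retained[:, j])[0]
        rows_subj.append(subject_id[idx])
        rows_month.append(np.full(idx.size, g.visit_months[j + 1]))
        rows_t.append(nominal[idx, j])
    sid = np.concatenate(rows_subj)
    month = np.concatenate(rows_month)
    t = np.concatenate(rows_t)

    pos = {s: i for i, s in enumerate(subject_id)}
    loc = np.array([pos[s] for s in sid])
    scale = np.sqrt(t) if cfg.resid_scales_with_interval else 1.0
    y_brain = rates["brain"][loc] * t + rng.normal(0.0, g.resid_sd_brain, sid.size) * scale
    y_hippo = rates["hippo"][loc] * t + rng.normal(0.0, g.resid_sd_hippo, sid.size) * scale

    observations = pd.DataFrame({
        "subject_id": sid,
        "visit_month": month,
        "interval_years": t,
        "bsi_brain_ml": y_brain,
        "bsi_hippo_ml": y_hippo,
    }).sort_values(["subject_id", "visit_month"], kind="stable").reset_index(drop=True)

    return subjects, observations


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort from ``config``; reproducible from ``config.seed``.

    Returns a :class:`Cohort` with a subjects table (baseline covariates
    and latent generating rates) and an observations table (one row per
    baseline-to-follow-up scan pair with BSI outcomes in ml).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    subj_frames, obs_frames = [], []
    offset = 0
    for g in config.groups:
        s, o = _generate_group(g, config, rng, offset)
        subj_frames.append(s)
        obs_frames.append(o)
        offset += g.n
    subjects = pd.concat(subj_frames, ignore_index=True)
    observations = pd.concat(obs_frames, ignore_index=True)
    return Cohort(subjects[SUBJECT_COLUMNS], observations[OBSERVATION_COLUMNS])


def write_cohort(cohort: Cohort, out_dir) -> tuple[str, str]:
    """Write subjects.csv and observations.csv (volumes in ml, rates ml/yr)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    spath = os.path.join(out_dir, "subjects.csv")
    opath = os.path.join(out_dir, "observations.csv")
    cohort.subjects.to_csv(spath, index=False)
    cohort.observations.to_csv(opath, index=False)
    return spath, opath


def read_cohort(subjects_csv, observations_csv) -> Cohort:
    # round_trip parsing reproduces the written float64 values exactly,
    # so analyses of a reloaded cohort are bit-identical to in-memory runs
    subjects = pd.read_csv(subjects_csv, float_precision="round_trip")
    observations = pd.read_csv(observations_csv, float_precision="round_trip")
    return Cohort(subjects, observations)
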