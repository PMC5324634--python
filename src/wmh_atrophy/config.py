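"""Cohort configuration and calibration presets.

The synthetic cohorts emulate the structure of a three-group ageing /
dementia study (cognitively normal controls, mild cognitive impairment,
Alzheimer's disease) with serial MRI at nominal visits, baseline white
matter hyperintensity (WMH) burden analysed per doubling (log2 ml),
total intracranial volume (TIV) as a head-size covariate, and an
optional cerebrospinal-fluid (CSF) biomarker subset.

All volumes are in ml, rates in ml/year, CSF concentrations in pg/ml.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

# Conventional conversion between an inter-quartile range and a normal SD
IQR_TO_SD = 1.0 / 1.349


@dataclass
class BaselineModel:
    """Linear model for a baseline structural volume.

    volume = intercept + beta_tiv * (TIV - mu_TIV)
                       + beta_wmh * (log2WMH - mu_W)
                       + beta_male * 1[male] + Normal(0, resid_sd)

    ``intercept`` is therefore the mean volume of a female subject with
    average TIV and average WMH burden.
    """

    intercept: float
    beta_tiv: float
    beta_wmh: float
    resid_sd: float
    beta_male: float = 0.0


@dataclass
class RateModel:
    """Mean-rate model for one outcome (ml of tissue lost per year).

    rate = alpha + beta_wmh * (log2WMH - mu_W)
                 + beta_tiv * (TIV - mu_TIV)
                 + gamma_tiv_wmh * (TIV - mu_TIV)/100 * (log2WMH - mu_W)
                 + beta_ab42 * (Abeta42 - mu_Ab)/10
                 + beta_tau  * (tau - mu_tau)/10
                 + beta_age  * (age - mu_age) + sum_k beta_vrf[k] * vrf_k
                 + b                      (subject-level random slope)

    ``alpha`` is the mean atrophy rate of a subject at the average of
    every continuous covariate; ``beta_wmh`` is in ml/yr per doubling of
    WMH; CSF effects are per 10 pg/ml; ``gamma_tiv_wmh`` is the change
    in the WMH effect per 100 ml of TIV.
    """

    alpha: float
    beta_wmh: float
    beta_tiv: float = 0.0
    gamma_tiv_wmh: float = 0.0
    beta_ab42: float = 0.0
    beta_tau: float = 0.0
    beta_age: float = 0.0
    beta_vrf: tuple[float, float, float, float, float] = (0.0,) * 5


#: order of the vascular-risk-factor flags everywhere in the package
VRF_NAMES = ("hypertension", "hypercholesterolemia", "diabetes", "smoking", "apoe4")


@dataclass
class GroupParams:
    """Generating parameters for one diagnostic group."""

    name: str
    n: int
    age_mean: float
    age_sd: float
    male_fraction: float
    mmse_mean: float
    mmse_sd: float
    tiv_mean_ml: float
    tiv_sd_ml: float
    log2wmh_mean: float
    log2wmh_sd: float
    baseline_brain: BaselineModel
    baseline_hippo: BaselineModel
    rate_brain: RateModel
    rate_hippo: RateModel
    # random-slope covariance: SDs (ml/yr) and correlation between the
    # whole-brain and hippocampal slopes
    slope_sd_brain: float = 3.3
    slope_sd_hippo: float = 0.044
    slope_corr: float = 0.5
    # BSI measurement error SD per scan pair (ml)
    resid_sd_brain: float = 2.0
    resid_sd_hippo: float = 0.02
    visit_months: tuple[int, ...] = (0, 6, 12, 24, 36)
    # conditional probability of attending each follow-up visit given the
    # previous one was attended (monotone dropout); first entry is the
    # 6-month visit
    retention: tuple[float, ...] = (1.0, 0.93, 0.88, 0.80)
    csf_fraction: float = 0.5
    csf_ab42_mean: float = 205.0
    csf_ab42_sd: float = 55.0
    csf_tau_mean: float = 70.0
    csf_tau_sd: float = 30.0
    vrf_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(zip(VRF_NAMES, (0.42, 0.25, 0.06, 0.40, 0.26)))
    )

    def slope_cov(self) -> np.ndarray:
        """2x2 covariance of the (brain, hippocampus) random slopes."""
        off = self.slope_corr * self.slope_sd_brain * self.slope_sd_hippo
        return np.array(
            [
                [self.slope_sd_brain**2, off],
                [off, self.slope_sd_hippo**2],
            ]
        )

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.name!r}: n must be positive")
        if len(self.visit_months) < 2:
            raise ValueError(f"group {self.name!r}: need baseline plus >=1 follow-up visit")
        if list(self.visit_months) != sorted(set(self.visit_months)):
            raise ValueError(f"group {self.name!r}: visit_months must be strictly increasing")
        if len(self.retention) != len(self.visit_months) - 1:
            raise ValueError(
                f"group {self.name!r}: retention needs one entry per follow-up visit"
            )
        if any(not (0.0 <= r <= 1.0) for r in self.retention):
            raise ValueError(f"group {self.name!r}: retention probabilities must be in [0, 1]")
        for nm in ("age_sd", "tiv_sd_ml", "log2wmh_sd", "resid_sd_brain", "resid_sd_hippo",
                   "slope_sd_brain", "slope_sd_hippo", "csf_ab42_sd", "csf_tau_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"group {self.name!r}: {nm} must be >= 0")
        if not -1.0 <= self.slope_corr <= 1.0:
            raise ValueError(f"group {self.name!r}: slope correlation outside [-1, 1]")
        cov = self.slope_cov()
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError(f"group {self.name!r}: slope covariance not PSD")
        if not 0.0 <= self.csf_fraction <= 1.0:
            raise ValueError(f"group {self.name!r}: csf_fraction outside [0, 1]")


@dataclass
class CohortConfig:
    """Full cohort-generator configuration (one or more groups)."""

    groups: list[GroupParams]
    seed: int = 0
    interval_jitter_yr: float = 0.05
    #: strength of dependence of dropout on the latent brain atrophy rate
    #: (log-odds of retention shift per SD of the brain random slope);
    #: 0 gives dropout completely at random, >0 gives faster-atrophying
    #: subjects a higher dropout hazard (missing at random given the
    #: latent rate)
    mar_strength: float = 0.0
    #: if True the BSI error SD scales with sqrt(interval) instead of
    #: being constant per scan pair
    resid_scales_with_interval: bool = False

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for g in self.groups:
            g.validate()
        if self.interval_jitter_yr < 0:
            raise ValueError("interval_jitter_yr must be >= 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        groups = []
        for g in d["groups"]:
            g = dict(g)
            for key, sub in (("baseline_brain", BaselineModel), ("baseline_hippo", BaselineModel),
                             ("rate_brain", RateModel), ("rate_hippo", RateModel)):
                if isinstance(g[key], dict):
                    sub_d = dict(g[key])
                    if "beta_vrf" in sub_d and sub_d["beta_vrf"] is not None:
                        sub_d["beta_vrf"] = tuple(sub_d["beta_vrf"])
                    g[key] = sub(**sub_d)
            for key in ("visit_months", "retention"):
                g[key] = tuple(g[key])
            groups.append(GroupParams(**g))
        rest = {k: v for k, v in d.items() if k != "groups"}
        return cls(groups=groups, **rest)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Calibration presets.
#
# The group-level means/SDs (age, TIV, baseline volumes, WMH burden, risk
# factor prevalences) and the rate-model coefficients are set so the
# generated cohorts reproduce the demographic structure and the fitted
# associations of a large three-group ageing cohort: control mean
# hippocampal volume 5.2 ml, whole-brain atrophy 6.31 ml/yr, hippocampal
# atrophy 0.07 ml/yr, a WMH association of 0.3 (brain) and 0.005
# (hippocampus) ml/yr per doubling, and so on.  WMH burden is drawn on
# the log2 scale, with the location set to the reported median and the
# scale to IQR/1.349.
#
# Slope SDs are calibrated so Wald CIs of the mean rates match reported
# interval widths at the group sizes; the slope correlation and the brain
# WMH coefficient jointly fix the conditional (brain-adjusted) WMH
# coefficient for the hippocampus at its reported value
#   beta_H|B = beta_H,W - (sigma_HB / sigma_BB) * beta_B,W .
# ---------------------------------------------------------------------------


def control_params(n: int = 198, **overrides) -> GroupParams:
    """Control-group calibration.

    The implied conditional (brain-adjusted) hippocampal WMH coefficient
    is 0.005 - (0.5 * 0.044 / 3.3) * 0.3 = 0.003 ml/yr per doubling.
    """
    p = GroupParams(
        name="control",
        n=n,
        age_mean=75.9, age_sd=5.1,
        male_fraction=0.525,
        mmse_mean=29.1, mmse_sd=1.0,
        tiv_mean_ml=1445.0, tiv_sd_ml=134.0,
        log2wmh_mean=-2.37, log2wmh_sd=2.3 * IQR_TO_SD,
        baseline_brain=BaselineModel(intercept=1068.0, beta_tiv=0.5,
                                     beta_wmh=-3.41, resid_sd=41.0),
        baseline_hippo=BaselineModel(intercept=5.2, beta_tiv=0.0015,
                                     beta_wmh=-0.06, resid_sd=0.48),
        rate_brain=RateModel(alpha=6.31, beta_wmh=0.3, beta_tiv=0.004),
        rate_hippo=RateModel(alpha=0.07, beta_wmh=0.005, beta_tiv=0.00005),
        slope_sd_brain=3.3, slope_sd_hippo=0.044, slope_corr=0.5,
        resid_sd_brain=2.0, resid_sd_hippo=0.02,
        visit_months=(0, 6, 12, 24, 36),
        retention=(1.0, 0.93, 0.88, 0.80),
        vrf_prevalence=dict(zip(VRF_NAMES, (0.42, 0.25, 0.06, 0.40, 0.26))),
    )
    return dataclasses.replace(p, **overrides)


def mci_params(n: int = 345, **overrides) -> GroupParams:
    """MCI-group calibration.

    The brain WMH coefficient is set inside its reported uncertainty
    interval so that, with slope SDs matched to the reported rate CIs,
    the conditional hippocampal WMH coefficient equals its reported
    0.003: 0.005 - (0.63 * 0.1 / 6.3) * 0.2 = 0.003.
    """
    p = GroupParams(
        name="mci",
        n=n,
        age_mean=75.0, age_sd=7.2,
        male_fraction=0.632,
        mmse_mean=27.0, mmse_sd=1.8,
        tiv_mean_ml=1468.0, tiv_sd_ml=146.0,
        log2wmh_mean=-2.08, log2wmh_sd=2.4 * IQR_TO_SD,
        baseline_brain=BaselineModel(intercept=1061.0, beta_tiv=0.5,
                                     beta_wmh=-5.95, resid_sd=41.0),
        baseline_hippo=BaselineModel(intercept=4.4, beta_tiv=0.0015,
                                     beta_wmh=-0.08, resid_sd=0.55),
        rate_brain=RateModel(alpha=10.69, beta_wmh=0.2, beta_tiv=0.004),
        rate_hippo=RateModel(alpha=0.14, beta_wmh=0.005, beta_tiv=0.00005),
        slope_sd_brain=6.3, slope_sd_hippo=0.1, slope_corr=0.63,
        resid_sd_brain=2.0, resid_sd_hippo=0.02,
        visit_months=(0, 6, 12, 18, 24, 36),
        retention=(1.0, 0.92, 0.82, 0.80, 0.62),
        vrf_prevalence=dict(zip(VRF_NAMES, (0.50, 0.30, 0.07, 0.41, 0.55))),
    )
    return dataclasses.replace(p, **overrides)


def ad_params(n: int = 154, **overrides) -> GroupParams:
    """AD-group calibration (conditional WMH coefficient ~ -0.001)."""
    p = GroupParams(
        name="ad",
        n=n,
        age_mean=75.0, age_sd=7.7,
        male_fraction=0.539,
        mmse_mean=23.4, mmse_sd=1.9,
        tiv_mean_ml=1450.0, tiv_sd_ml=163.0,
        log2wmh_mean=-1.37, log2wmh_sd=2.2 * IQR_TO_SD,
        baseline_brain=BaselineModel(intercept=1022.0, beta_tiv=0.5,
                                     beta_wmh=-6.61, resid_sd=41.0),
        baseline_hippo=BaselineModel(intercept=3.9, beta_tiv=0.0015,
                                     beta_wmh=-0.09, resid_sd=0.55),
        rate_brain=RateModel(alpha=15.08, beta_wmh=0.06, beta_tiv=0.004),
        rate_hippo=RateModel(alpha=0.20, beta_wmh=-0.0005, beta_tiv=0.00005),
        slope_sd_brain=6.0, slope_sd_hippo=0.1, slope_corr=0.5,
        resid_sd_brain=2.5, resid_sd_hippo=0.02,
        visit_months=(0, 6, 12, 24),
        retention=(1.0, 0.80, 0.62),
        vrf_prevalence=dict(zip(VRF_NAMES, (0.52, 0.36, 0.06, 0.40, 0.69))),
    )
    return dataclasses.replace(p, **overrides)


def csf_control_params(n: int = 100, **overrides) -> GroupParams:
    """Control CSF-biomarker subset calibration.

    Rates depend additionally on CSF Abeta42 and tau (per 10 pg/ml).
    The slope SDs give a conditional hippocampal WMH coefficient of
    0.008 - (0.5 * 0.066 / 3.3) * 0.3 = 0.005 ml/yr per doubling.
    """
    p = control_params(
        n=n,
        csf_fraction=1.0,
        rate_brain=RateModel(alpha=6.25, beta_wmh=0.3, beta_tiv=0.004,
                             beta_ab42=-0.2, beta_tau=0.2),
        rate_hippo=RateModel(alpha=0.06, beta_wmh=0.008, beta_tiv=0.00005,
                             beta_ab42=-0.001, beta_tau=0.005),
        slope_sd_brain=3.3, slope_sd_hippo=0.066, slope_corr=0.5,
    )
    return dataclasses.replace(p, **overrides)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Full three-group cohort (198 controls, 345 MCI, 154 AD)."""
    return CohortConfig(groups=[control_params(), mci_params(), ad_params()], seed=seed)
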