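import dataclasses

import pytest

import wmh_atrophy as wa


@pytest.fixture(scope="session")
def control_cohort():
    """One calibrated control cohort (n=198), fixed seed."""
    return wa.generate_cohort(wa.CohortConfig(groups=[wa.control_params()], seed=42))


@pytest.fixture(scope="session")
def control_fits(control_cohort):
    c = control_cohort
    dB = wa.build_design(c.subjects, c.observations, outcome="brain")
    dH = wa.build_design(c.subjects, c.observations, outcome="hippo")
    return {"design_brain": dB, "design_hippo": dH,
            "brain": wa.fit_rate_lmm(dB), "hippo": wa.fit_rate_lmm(dH)}


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced grid keeps morphology cheap in unit tests."""
    return wa.ShapeSpec(shape=(48, 48, 48), brain_radius_mm=18.0,
                        hippo_semiaxes_mm=(6.0, 4.0, 4.0))


def deterministic_group(**overrides):
    """A noise-free control-like group for exact-value tests."""
    g = wa.control_params(n=20)
    g = dataclasses.replace(
        g, age_sd=0.0, tiv_sd_ml=0.0, log2wmh_sd=0.0,
        baseline_brain=dataclasses.replace(g.baseline_brain, resid_sd=0.0),
        baseline_hippo=dataclasses.replace(g.baseline_hippo, resid_sd=0.0),
        rate_brain=wa.RateModel(alpha=6.0, beta_wmh=0.0),
        rate_hippo=wa.RateModel(alpha=0.07, beta_wmh=0.0),
        slope_sd_brain=0.0, slope_sd_hippo=0.0,
        resid_sd_brain=0.0, resid_sd_hippo=0.0,
        visit_months=(0, 12), retention=(1.0,),
    )
    return dataclasses.replace(g, **overrides)
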