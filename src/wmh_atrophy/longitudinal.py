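"""Through-origin random-slope mixed models for atrophy rates.

The outcome of a scan pair is the tissue volume (ml) lost between
baseline and a follow-up scan, and every model term multiplies the
scan interval t (years), so each coefficient is an effect on the
*annual rate* of loss and the fitted change at t = 0 is exactly zero:

    y_ij = t_ij * (alpha + x_i' beta + b_i) + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2).

``fit_rate_lmm`` maximizes the marginal likelihood (ML, so nested fits
are comparable by likelihood-ratio test), profiling the fixed effects
by generalized least squares and optimizing the variance components on
the log scale.  ``fit_joint_lmm`` extends this to two outcomes (whole
brain and hippocampus) with a jointly normal slope pair
(b_B, b_H) ~ N(0, Sigma), fitted with a log-Cholesky parameterization
of Sigma; subjects missing one outcome contribute their marginal
likelihood (valid under missingness at random).

Because every model matrix row is t_ij times a subject-level covariate
vector, each subject's likelihood contribution reduces to a handful of
scalars (sum t^2, t'y, y'y), and fits are vectorized across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

Z95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class LongDesign:
    """Longitudinal design for one outcome.

    Subject-level covariates (all constant within subject) enter the
    model only through their interaction with the scan interval.  The
    leading covariate column is the constant 1, whose coefficient is
    the mean atrophy rate; continuous covariates are centered at the
    sample mean so that the mean rate refers to an average subject.
    """

    subject_ids: np.ndarray          # (n,) unique ids
    u: np.ndarray                    # (n, p) per-subject covariates incl. leading 1
    names: list[str]
    obs_subject: np.ndarray          # (N,) index into subject_ids
    t: np.ndarray                    # (N,) intervals in years
    y: np.ndarray                    # (N,) volume lost (ml)
    outcome: str = ""
    centers: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.t <= 0):
            raise ValueError("scan intervals must be strictly positive")
        if len(self.names) != self.u.shape[1]:
            raise ValueError("covariate names do not match design width")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def sufficient_stats(self):
        """Per-subject (count, sum t^2, t'y, y'y)."""
        n = self.n_subjects
        k = np.bincount(self.obs_subject, minlength=n).astype(float)
        s = np.bincount(self.obs_subject, weights=self.t**2, minlength=n)
        q = np.bincount(self.obs_subject, weights=self.t * self.y, minlength=n)
        w = np.bincount(self.obs_subject, weights=self.y**2, minlength=n)
        return k, s, q, w


def build_design(subjects: pd.DataFrame, observations: pd.DataFrame,
                 outcome: str = "hippo", csf: bool = False,
                 tiv_wmh_interaction: bool = False,
                 covariates: tuple[str, ...] = ("log2wmh", "tiv"),
                 center: bool = True) -> LongDesign:
    """Assemble a :class:`LongDesign` from cohort tables.

    Parameters
    ----------
    outcome:
        ``"hippo"`` or ``"brain"``; selects the BSI column.
    csf:
        add Abeta42/10 and tau/10 covariates and restrict to subjects
        with CSF data.
    tiv_wmh_interaction:
        add a (TIV/100 ml) x log2WMH product term (both centered), so
        its coefficient is the change in the WMH effect per 100 ml TIV.
    covariates:
        base covariate set; ``"tiv"`` enters in ml, ``"age"`` in years,
        any vascular-risk flag by its column name.
    """
    ycol = {"hippo": "bsi_hippo_ml", "brain": "bsi_brain_ml"}[outcome]
    subj = subjects
    if csf:
        subj = subj[subj["csf_available"].astype(bool)]
    subj = subj.reset_index(drop=True)
    obs = observations[observations["subject_id"].isin(subj["subject_id"])]
    obs = obs[np.isfinite(obs[ycol])].reset_index(drop=True)
    keep = subj["subject_id"].isin(obs["subject_id"])
    subj = subj[keep].reset_index(drop=True)

    if len(subj) < 2:
        raise ValueError("need at least two subjects with observations")

    centers: dict[str, float] = {}

    def centered(series, name, scale=1.0):
        x = np.asarray(series, dtype=float) / scale
        mu = x.mean() if center else 0.0
        centers[name] = mu
        return x - mu

    cols = [np.ones(len(subj))]
    names = ["rate"]
    col_map = {}
    for cv in covariates:
        if cv == "log2wmh":
            col_map["log2wmh"] = centered(subj["log2wmh"], "log2wmh")
        elif cv == "tiv":
            col_map["tiv"] = centered(subj["tiv_ml"], "tiv")
        elif cv == "age":
            col_map["age"] = centered(subj["age_years"], "age")
        else:
            col_map[cv] = np.asarray(subj[cv], dtype=float)
        cols.append(col_map[cv])
        names.append(cv)
    if csf:
        for raw, nm in (("csf_ab42_pg_ml", "ab42_per10"), ("csf_tau_pg_ml", "tau_per10")):
            cols.append(centered(subj[raw], nm, scale=10.0))
            names.append(nm)
    if tiv_wmh_interaction:
        if "tiv" not in col_map or "log2wmh" not in col_map:
            raise ValueError("TIVxWMH interaction requires tiv and log2wmh covariates")
        cols.append((col_map["tiv"] / 100.0) * col_map["log2wmh"])
        names.append("tiv_x_log2wmh_per100ml")

    u = np.column_stack(cols)
    pos = {s: i for i, s in enumerate(subj["subject_id"])}
    obs_subject = np.array([pos[s] for s in obs["subject_id"]])
    return LongDesign(
        subject_ids=subj["subject_id"].to_numpy(),
        u=u, names=names, obs_subject=obs_subject,
        t=obs["interval_years"].to_numpy(dtype=float),
        y=obs[ycol].to_numpy(dtype=float),
        outcome=outcome, centers=centers,
    )


def drop_covariates(design: LongDesign, drop: tuple[str, ...]) -> LongDesign:
    """Return a nested design with the named covariates removed."""
    keep = [i for i, nm in enumerate(design.names) if nm not in drop]
    if len(keep) == len(design.names):
        raise ValueError(f"none of {drop} present in design")
    return LongDesign(design.subject_ids, design.u[:, keep],
                      [design.names[i] for i in keep],
                      design.obs_subject, design.t, design.y,
                      design.outcome, design.centers)


# ---------------------------------------------------------------------------
# univariate fit
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """A fitted through-origin random-slope mixed model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    sigma_b: float
    sigma_e: float
    loglik: float
    cov_beta: np.ndarray
    n_subjects: int
    n_obs: int
    converged: bool
    boundary_sigma_b: bool
    design: LongDesign

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.names, "estimate": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        })


def _profile_negll(log_sb, log_se, k, s, q, w, U):
    """Profiled -2-free negative log-likelihood and the GLS solution."""
    sb2 = np.exp(2.0 * log_sb)
    se2 = np.exp(2.0 * log_se)
    d = se2 + sb2 * s
    A = (U * (s / d)[:, None]).T @ U
    c = U.T @ (q / d)
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    m = U @ beta
    rss = w - 2.0 * m * q + m**2 * s
    tr = q - m * s
    quad = (rss - (sb2 / d) * tr**2) / se2
    N = k.sum()
    ll = -0.5 * (N * np.log(2 * np.pi) + np.sum((k - 1) * np.log(se2) + np.log(d))
                 + quad.sum())
    return -ll, beta, A


def loglik_at(design: LongDesign, beta: np.ndarray, sigma_b: float,
              sigma_e: float) -> float:
    """Marginal log-likelihood at arbitrary parameter values."""
    k, s, q, w = design.sufficient_stats()
    sb2, se2 = sigma_b**2, sigma_e**2
    d = se2 + sb2 * s
    m = design.u @ beta
    rss = w - 2.0 * m * q + m**2 * s
    tr = q - m * s
    quad = (rss - (sb2 / d) * tr**2) / se2
    N = k.sum()
    return float(-0.5 * (N * np.log(2 * np.pi)
                         + np.sum((k - 1) * np.log(se2) + np.log(d)) + quad.sum()))


def fit_rate_lmm(design: LongDesign) -> LmmFit:
    """Maximum-likelihood fit of the through-origin rate model.

    Raises ``RuntimeError`` on non-convergence.  When the random-slope
    SD collapses to (numerically) zero, the fit is flagged
    ``boundary_sigma_b`` and the model reduces to weighted
    through-origin least squares.
    """
    k, s, q, w = design.sufficient_stats()
    U = design.u
    if np.linalg.matrix_rank(U) < U.shape[1]:
        raise ValueError("rank-deficient covariate matrix; drop collinear covariates")

    # two-stage starting values from per-subject OLS rates
    rate_i = q / s
    resid_scale = max(np.sqrt(np.mean(np.maximum(w - q**2 / s, 0.0) / np.maximum(k, 1))),
                      1e-10)
    var_rates = float(np.var(rate_i))
    sb0 = np.sqrt(max(var_rates - resid_scale**2 * np.mean(1.0 / s), 0.05 * var_rates,
                      1e-16))
    x0 = np.array([np.log(sb0), np.log(resid_scale)])
    scale_ref = np.log(max(resid_scale, sb0))
    bounds = [(scale_ref - 20.0, scale_ref + 6.0)] * 2

    def obj(x):
        return _profile_negll(x[0], x[1], k, s, q, w, U)[0]

    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"mixed-model fit did not converge: {res.message}; "
                           f"last iterate {res.x}")
    nll, beta, A = _profile_negll(res.x[0], res.x[1], k, s, q, w, U)
    sigma_b = float(np.exp(res.x[0]))
    sigma_e = float(np.exp(res.x[1]))
    boundary = bool(res.x[0] <= bounds[0][0] + 1e-6) or sigma_b < 1e-8 * sigma_e
    if boundary and not np.all(k == 1):
        warnings.warn("random-slope SD estimated at the zero boundary",
                      RuntimeWarning, stacklevel=2)
    if np.all(k == 1):
        # all-singleton subjects cannot separate sigma_b from sigma_e
        warnings.warn("all subjects have a single observation; sigma_b is not "
                      "identified and may sit at a boundary", RuntimeWarning,
                      stacklevel=2)

    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    return LmmFit(
        names=list(design.names), beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        p=2.0 * stats.norm.sf(np.abs(z)),
        sigma_b=sigma_b, sigma_e=sigma_e, loglik=float(-nll),
        cov_beta=cov_beta, n_subjects=design.n_subjects, n_obs=design.n_obs,
        converged=bool(res.success or np.isfinite(res.fun)),
        boundary_sigma_b=boundary, design=design,
    )


def blup_rates(fit: LmmFit) -> pd.DataFrame:
    """Per-subject predicted atrophy rates (empirical Bayes).

    rate_i = fixed-effect prediction + E[b_i | y_i]; the conditional
    mean shrinks the per-subject observed rate toward the population
    mean in proportion to the measurement noise.
    """
    d = fit.design
    k, s, q, w = d.sufficient_stats()
    sb2, se2 = fit.sigma_b**2, fit.sigma_e**2
    m = d.u @ fit.beta
    b_hat = sb2 * (q - m * s) / (se2 + sb2 * s)
    return pd.DataFrame({
        "subject_id": d.subject_ids,
        "predicted_rate_ml_yr": m + b_hat,
        "fixed_effect_rate_ml_yr": m,
        "random_effect_ml_yr": b_hat,
    })


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float
    loglik_full: float
    loglik_reduced: float


def likelihood_ratio_test(full, reduced, df: int | None = None) -> LrtResult:
    """Compare two nested ML fits; df defaults to the fixed-effect gap."""
    if df is None:
        df = len(full.names) - len(reduced.names)
        if hasattr(full, "names_brain"):
            df = (len(full.names_brain) + len(full.names_hippo)
                  - len(reduced.names_brain) - len(reduced.names_hippo))
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LrtResult(statistic=float(stat), df=int(df), p=p,
                     loglik_full=float(full.loglik),
                     loglik_reduced=float(reduced.loglik))


def fit_with_tiv_wmh_interaction(subjects: pd.DataFrame, observations: pd.DataFrame,
                                 outcome: str = "brain"):
    """Fit the TIV x WMH interaction model and its WMH-free reduction.

    Returns ``(full_fit, reduced_fit, lrt)``: the full model carries
    log2WMH x interval and (TIV/100) x log2WMH x interval terms; the
    reduced model drops both (df = 2), testing the overall WMH effect
    allowing it to vary with head size.
    """
    full_design = build_design(subjects, observations, outcome=outcome,
                               tiv_wmh_interaction=True)
    red_design = drop_covariates(full_design, ("log2wmh", "tiv_x_log2wmh_per100ml"))
    full = fit_rate_lmm(full_design)
    reduced = fit_rate_lmm(red_design)
    return full, reduced, likelihood_ratio_test(full, reduced, df=2)


# ---------------------------------------------------------------------------
# joint bivariate model
# ---------------------------------------------------------------------------

@dataclass
class JointFit:
    """Fitted bivariate random-slope model (whole brain + hippocampus)."""

    names_brain: list[str]
    names_hippo: list[str]
    beta_brain: np.ndarray
    beta_hippo: np.ndarray
    se_brain: np.ndarray
    se_hippo: np.ndarray
    Sigma: np.ndarray                # 2x2 slope covariance [[BB, BH], [HB, HH]]
    sigma_e_brain: float
    sigma_e_hippo: float
    loglik: float
    cov_beta: np.ndarray             # GLS covariance of (beta_B, beta_H)
    cov_full: np.ndarray             # observed-information covariance of (beta, theta)
    theta: np.ndarray                # (l11, l21, l22, log seB, log seH)
    converged: bool
    n_subjects: int
    _stats: dict

    @property
    def slope_corr(self) -> float:
        return float(self.Sigma[0, 1] / np.sqrt(self.Sigma[0, 0] * self.Sigma[1, 1]))

    def coef(self, outcome: str, name: str) -> float:
        if outcome == "brain":
            return float(self.beta_brain[self.names_brain.index(name)])
        return float(self.beta_hippo[self.names_hippo.index(name)])


class _JointData:
    """Per-subject scalar sufficient statistics for the bivariate model."""

    def __init__(self, design_brain: LongDesign, design_hippo: LongDesign):
        ids = np.union1d(design_brain.subject_ids, design_hippo.subject_ids)
        self.ids = ids
        n = len(ids)
        self.pB, self.pH = design_brain.u.shape[1], design_hippo.u.shape[1]
        self.names_brain = list(design_brain.names)
        self.names_hippo = list(design_hippo.names)
        self.UB = np.zeros((n, self.pB))
        self.UH = np.zeros((n, self.pH))
        self.kB = np.zeros(n)
        self.kH = np.zeros(n)
        self.sB = np.zeros(n)
        self.sH = np.zeros(n)
        self.qB = np.zeros(n)
        self.qH = np.zeros(n)
        self.wB = np.zeros(n)
        self.wH = np.zeros(n)
        for d, U, kk, ss, qq, ww in ((design_brain, self.UB, self.kB, self.sB,
                                      self.qB, self.wB),
                                     (design_hippo, self.UH, self.kH, self.sH,
                                      self.qH, self.wH)):
            k, s, q, w = d.sufficient_stats()
            loc = np.searchsorted(ids, d.subject_ids)
            U[loc] = d.u
            kk[loc], ss[loc], qq[loc], ww[loc] = k, s, q, w
        self.N = float(self.kB.sum() + self.kH.sum())

    def negll(self, theta, beta=None):
        """Negative log-likelihood; profiles beta by GLS when not given."""
        l11, l21, l22, lseB, lseH = theta
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        Sigma = L @ L.T
        seB2, seH2 = np.exp(2.0 * lseB), np.exp(2.0 * lseH)
        detS = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
        Sinv = np.array([[Sigma[1, 1], -Sigma[0, 1]],
                         [-Sigma[0, 1], Sigma[0, 0]]]) / detS
        dB = self.sB / seB2
        dH = self.sH / seH2
        # M_i = Sigma^-1 + diag(dB, dH), inverted in closed form
        m11 = Sinv[0, 0] + dB
        m22 = Sinv[1, 1] + dH
        m12 = Sinv[0, 1]
        detM = m11 * m22 - m12**2
        # G = D - D C D with C = M^-1
        c11, c22, c12 = m22 / detM, m11 / detM, -m12 / detM
        G00 = dB - dB * c11 * dB
        G11 = dH - dH * c22 * dH
        G01 = -dB * c12 * dH
        vB = self.qB / seB2
        vH = self.qH / seH2
        gB = vB - dB * (c11 * vB + c12 * vH)
        gH = vH - dH * (c12 * vB + c22 * vH)
        yVy = (self.wB / seB2 + self.wH / seH2
               - (c11 * vB**2 + 2.0 * c12 * vB * vH + c22 * vH**2))
        logdet = (self.kB * np.log(seB2) + self.kH * np.log(seH2)
                  + np.log(detS) + np.log(detM))

        pB = self.pB
        A = np.zeros((pB + self.pH, pB + self.pH))
        A[:pB, :pB] = (self.UB * G00[:, None]).T @ self.UB
        A[pB:, pB:] = (self.UH * G11[:, None]).T @ self.UH
        ABH = (self.UB * G01[:, None]).T @ self.UH
        A[:pB, pB:] = ABH
        A[pB:, :pB] = ABH.T
        c = np.concatenate([self.UB.T @ gB, self.UH.T @ gH])
        if beta is None:
            try:
                beta = np.linalg.solve(A, c)
            except np.linalg.LinAlgError:
                return np.inf, None, None
        quad = yVy.sum() - 2.0 * beta @ c + beta @ A @ beta
        nll = 0.5 * (self.N * np.log(2 * np.pi) + logdet.sum() + quad)
        return nll, beta, A


def _hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian with per-coordinate steps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_joint_lmm(design_brain: LongDesign, design_hippo: LongDesign) -> JointFit:
    """ML fit of the bivariate through-origin random-slope model."""
    data = _JointData(design_brain, design_hippo)

    # starting values from the univariate fits
    fb = fit_rate_lmm(design_brain)
    fh = fit_rate_lmm(design_hippo)
    sbB = max(fb.sigma_b, 1e-4 * fb.sigma_e, 1e-12)
    sbH = max(fh.sigma_b, 1e-4 * fh.sigma_e, 1e-12)
    rho0 = 0.3
    x0 = np.array([np.log(sbB), rho0 * sbH, np.log(sbH * np.sqrt(1 - rho0**2)),
                   np.log(fb.sigma_e), np.log(fh.sigma_e)])

    def obj(theta):
        return data.negll(theta)[0]

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000, "maxfev": 6000})
    res2 = optimize.minimize(obj, res.x, method="L-BFGS-B",
                             options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 300})
    theta = res2.x if res2.fun <= res.fun else res.x
    nll, beta, A = data.negll(theta)
    if not np.isfinite(nll):
        raise RuntimeError("joint mixed-model fit did not converge (flat likelihood)")

    l11, l21, l22, lseB, lseH = theta
    L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    Sigma = L @ L.T
    pB = data.pB

    cov_beta = np.linalg.inv(A)
    seB = np.sqrt(np.diag(cov_beta))[:pB]
    seH = np.sqrt(np.diag(cov_beta))[pB:]

    # observed-information covariance over the full parameter (beta, theta)
    def full_nll(phi):
        return data.negll(phi[len(beta):], beta=phi[:len(beta)])[0]

    phi = np.concatenate([beta, theta])
    H = _hessian(full_nll, phi)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)

    return JointFit(
        names_brain=data.names_brain, names_hippo=data.names_hippo,
        beta_brain=beta[:pB], beta_hippo=beta[pB:],
        se_brain=seB, se_hippo=seH,
        Sigma=Sigma, sigma_e_brain=float(np.exp(lseB)),
        sigma_e_hippo=float(np.exp(lseH)),
        loglik=float(-nll), cov_beta=cov_beta, cov_full=cov_full,
        theta=theta, converged=bool(res.success or res2.success),
        n_subjects=len(data.ids),
        _stats={"data": data, "beta": beta},
    )


def joint_loglik_at(fit_or_data, beta_brain, beta_hippo, Sigma,
                    sigma_e_brain, sigma_e_hippo) -> float:
    """Joint log-likelihood at arbitrary parameter values."""
    data = fit_or_data._stats["data"] if isinstance(fit_or_data, JointFit) else fit_or_data
    L = np.linalg.cholesky(np.asarray(Sigma, dtype=float))
    theta = np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]),
                      np.log(sigma_e_brain), np.log(sigma_e_hippo)])
    beta = np.concatenate([beta_brain, beta_hippo])
    return float(-data.negll(theta, beta=beta)[0])


@dataclass
class AdjustedAssociation:
    """A conditional (concurrent-atrophy-adjusted) WMH association."""

    target: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


def adjusted_association(fit: JointFit, target: str = "hippo",
                         covariate: str = "log2wmh") -> AdjustedAssociation:
    """WMH effect on one structure's rate given the other's rate.

    For the hippocampus adjusted for concurrent whole-brain atrophy the
    estimand is the covariate coefficient in the conditional mean of
    the hippocampal rate given the whole-brain rate,

        beta_H|B = beta_H - (sigma_HB / sigma_BB) * beta_B,

    with the analogous expression when the roles are swapped.  The
    standard error comes from the delta method over the joint
    observed-information covariance of the fixed effects and the
    log-Cholesky variance parameters.
    """
    if target not in ("hippo", "brain"):
        raise ValueError("target must be 'hippo' or 'brain'")
    var_idx = 0 if target == "hippo" else 1      # index of the conditioning outcome
    denom = fit.Sigma[var_idx, var_idx]
    scale = fit.Sigma[0, 0] if target == "hippo" else fit.Sigma[1, 1]
    if denom <= 1e-12 * max(scale, 1e-300):
        raise ValueError("conditioning outcome has (numerically) zero slope "
                         "variance; the adjusted estimand is undefined")

    iB = fit.names_brain.index(covariate)
    iH = fit.names_hippo.index(covariate)
    pB = len(fit.names_brain)

    def estimand(phi):
        bB = phi[iB]
        bH = phi[pB + iH]
        l11, l21, l22 = phi[pB + len(fit.names_hippo):][:3]
        s_BB = np.exp(2.0 * l11)
        s_HB = l21 * np.exp(l11)
        s_HH = l21**2 + np.exp(2.0 * l22)
        if target == "hippo":
            return bH - (s_HB / s_BB) * bB
        return bB - (s_HB / s_HH) * bH

    phi = np.concatenate([fit.beta_brain, fit.beta_hippo, fit.theta])
    est = float(estimand(phi))
    # numeric gradient for the delta method
    h = 1e-6 * np.maximum(np.abs(phi), 1.0)
    grad = np.empty_like(phi)
    for i in range(len(phi)):
        e = np.zeros_like(phi); e[i] = h[i]
        grad[i] = (estimand(phi + e) - estimand(phi - e)) / (2.0 * h[i])
    var = float(grad @ fit.cov_full @ grad)
    se = np.sqrt(max(var, 0.0))
    z = est / se if se > 0 else np.inf
    return AdjustedAssociation(
        target=target, estimate=est, se=se,
        ci_low=est - Z95 * se, ci_high=est + Z95 * se,
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


def fit_with_csf(subjects: pd.DataFrame, observations: pd.DataFrame,
                 joint: bool = True):
    """Fit the CSF-augmented model on the biomarker subset.

    Adds (Abeta42/10) x interval and (tau/10) x interval terms to the
    fixed effects and restricts to subjects with CSF measurements.
    Returns a :class:`JointFit` (default) or the pair of univariate
    :class:`LmmFit` objects when ``joint=False``.
    """
    dB = build_design(subjects, observations, outcome="brain", csf=True)
    dH = build_design(subjects, observations, outcome="hippo", csf=True)
    if joint:
        return fit_joint_lmm(dB, dH)
    return fit_rate_lmm(dB), fit_rate_lmm(dH)
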