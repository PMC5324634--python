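"""Baseline (cross-sectional) volume models and group comparisons.

The baseline association model regresses a structural volume (whole
brain or hippocampus, ml) on log2 WMH burden with TIV and gender as
covariates, so the WMH coefficient is the volume difference per
doubling of WMH.  Continuous covariates are centered and females are
the reference gender, making the intercept the adjusted mean volume
for a female subject with average TIV and WMH.

Group demographics are compared by ANOVA-style OLS F-tests for
continuous variables (optionally TIV-adjusted) and by Fisher's exact
test (Freeman-Halton extension for r x c tables) for categorical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass
class RegressionFit:
    """An ordinary least-squares fit with t-based inference."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    resid_sd: float
    df_resid: int
    n: int
    adjusted_mean: float

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.names, "estimate": self.beta,
                             "se": self.se, "ci_low": self.ci_low,
                             "ci_high": self.ci_high, "p": self.p})


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify the offending columns by dropping one at a time
        bad = [names[j] for j in range(p)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df if df > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    return beta, resid, s2, df, XtX_inv


def fit_baseline_model(subjects: pd.DataFrame, outcome: str = "hippo") -> RegressionFit:
    """OLS of a baseline volume on log2WMH, centered TIV and gender.

    ``adjusted_mean`` is the model intercept: the expected volume of a
    female with mean TIV and mean WMH burden.
    """
    ycol = {"hippo": "baseline_hippo_ml", "brain": "baseline_brain_ml"}[outcome]
    df = subjects.dropna(subset=[ycol, "log2wmh", "tiv_ml"]).reset_index(drop=True)
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    male = (df["gender"] == "male").to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(n),
        df["log2wmh"].to_numpy(dtype=float) - df["log2wmh"].mean(),
        df["tiv_ml"].to_numpy(dtype=float) - df["tiv_ml"].mean(),
        male,
    ])
    names = ["intercept", "log2wmh", "tiv", "male"]
    y = df[ycol].to_numpy(dtype=float)
    beta, resid, s2, dfres, XtX_inv = _ols(X, y, names)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    tcrit = stats.t.ppf(0.975, dfres)
    tstat = beta / se
    return RegressionFit(
        names=names, beta=beta, se=se,
        ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
        p=2.0 * stats.t.sf(np.abs(tstat), dfres),
        resid_sd=float(np.sqrt(s2)), df_resid=dfres, n=n,
        adjusted_mean=float(beta[0]),
    )


@dataclass
class GroupComparison:
    statistic: float
    df_num: int
    df_den: int
    p: float
    degenerate: bool = False


def compare_groups_continuous(subjects: pd.DataFrame, variable: str,
                              adjust_tiv: bool = False) -> GroupComparison:
    """ANOVA-style F-test of group differences in a continuous variable."""
    df = subjects.dropna(subset=[variable]).reset_index(drop=True)
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = df["group"].value_counts()
    if counts.min() < 2:
        raise ValueError("every group needs at least two subjects")
    n = len(df)
    y = df[variable].to_numpy(dtype=float)
    dummies = np.column_stack([(df["group"] == g).to_numpy(dtype=float)
                               for g in groups[1:]])
    base = [np.ones(n)]
    if adjust_tiv:
        base.append(df["tiv_ml"].to_numpy(dtype=float) - df["tiv_ml"].mean())
    X0 = np.column_stack(base)
    X1 = np.column_stack(base + [dummies])

    rss = []
    for X in (X0, X1):
        b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        rss.append(float(r @ r))
    df_num = X1.shape[1] - X0.shape[1]
    df_den = n - X1.shape[1]
    if rss[1] <= 1e-12 * max(float(y @ y), 1.0):
        warnings.warn("zero residual variance; F statistic undefined",
                      RuntimeWarning, stacklevel=2)
        return GroupComparison(np.nan, df_num, df_den, np.nan, degenerate=True)
    F = ((rss[0] - rss[1]) / df_num) / (rss[1] / df_den)
    return GroupComparison(float(F), df_num, df_den,
                           float(stats.f.sf(F, df_num, df_den)))


# ---------------------------------------------------------------------------
# Fisher's exact test (Freeman-Halton) by enumeration with MC fallback
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, row: np.ndarray, col: np.ndarray,
                    n: int) -> float:
    # P(T | margins) = prod(row!) prod(col!) / (n! prod(cells!))
    return (gammaln(row + 1).sum() + gammaln(col + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def _enumerate_pvalue(row, col, logp_obs):
    """Sum the null probabilities of all margin-fixed tables no more
    probable than the observed one (recursion over the free cells)."""
    r, c = len(row), len(col)
    n = int(row.sum())
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    tol = 1e-7 * max(abs(logp_obs), 1.0)
    total = 0.0

    colrem = col.astype(int).copy()

    def rec(i, j, rowrem_i, logfact):
        nonlocal total
        # filling row i, cell j; rowrem_i = remainder of row i
        if i == r - 1:
            # last row forced by column remainders
            lf = logfact + gammaln(colrem + 1).sum()
            logp = const - lf
            if logp <= logp_obs + tol:
                total += np.exp(logp)
            return
        if j == c - 1:
            x = rowrem_i
            if x > colrem[j]:
                return
            colrem[j] -= x
            rec(i + 1, 0, int(row[i + 1]), logfact + gammaln(x + 1))
            colrem[j] += x
            return
        hi = min(rowrem_i, colrem[j])
        for x in range(hi + 1):
            colrem[j] -= x
            rec(i, j + 1, rowrem_i - x, logfact + gammaln(x + 1))
            colrem[j] += x

    rec(0, 0, int(row[0]), 0.0)
    return min(total, 1.0)


@dataclass
class FisherResult:
    p: float
    method: str                  # "enumeration" or "monte_carlo"
    n_tables: int | None = None
    n_replicates: int | None = None
    seed: int | None = None


def compare_groups_categorical(counts, enumeration_budget: int = 10_000_000,
                               mc_replicates: int = 100_000,
                               seed: int = 0) -> FisherResult:
    """Fisher's exact test for an r x c contingency table.

    The p-value is the total null probability (margins fixed) of all
    tables at most as probable as the observed one.  Exact enumeration
    is used when the table-count bound fits the budget; otherwise a
    seeded Monte-Carlo permutation estimate is returned.
    """
    table = np.asarray(counts, dtype=int)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("counts must be a nonnegative 2-D table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("dropping empty rows/columns", RuntimeWarning, stacklevel=2)
        table = table[row > 0][:, col > 0]
        row, col = table.sum(axis=1), table.sum(axis=0)
    if table.size <= 1 or min(table.shape) < 2:
        return FisherResult(p=1.0, method="enumeration", n_tables=1)
    n = int(table.sum())
    logp_obs = _log_table_prob(table, row, col, n)

    # crude upper bound on the number of tables to enumerate
    bound = 1.0
    for i in range(table.shape[0] - 1):
        for j in range(table.shape[1] - 1):
            bound *= min(row[i], col[j]) + 1
            if bound > enumeration_budget:
                break
        if bound > enumeration_budget:
            break

    if bound <= enumeration_budget:
        p = _enumerate_pvalue(row, col, logp_obs)
        return FisherResult(p=float(p), method="enumeration", n_tables=int(bound))

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(col)), col)
    starts = np.concatenate([[0], np.cumsum(row)])
    tol = 1e-7 * max(abs(logp_obs), 1.0)
    hits = 0
    for _ in range(mc_replicates):
        perm = rng.permutation(labels)
        t = np.stack([np.bincount(perm[starts[i]:starts[i + 1]], minlength=len(col))
                      for i in range(len(row))])
        if _log_table_prob(t, row, col, n) <= logp_obs + tol:
            hits += 1
    # add-one estimate keeps the p-value away from an impossible zero
    p = (hits + 1) / (mc_replicates + 1)
    return FisherResult(p=float(p), method="monte_carlo",
                        n_replicates=mc_replicates, seed=seed)
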