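"""Pipeline orchestration: simulate -> analyse -> tabulate.

Runs the cohort generator, the cross-sectional and longitudinal model
stages and the plotting stage, writing publication-style CSV tables
and a manifest with SHA-256 hashes and the per-stage seeds, so a rerun
with the same configuration is bit-identical for every deterministic
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cross_sectional as xs
from . import longitudinal as lg
from .cohort import Cohort, generate_cohort, write_cohort
from .config import CohortConfig, default_cohort_config

# fixed per-stage seed offsets fanned out from the global seed
STAGE_SEED_OFFSETS = {"simulate": 1, "phantom": 2, "fisher_mc": 3, "recovery": 4}

ALL_STAGES = ("simulate", "cross-sectional", "longitudinal", "plots")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=default_cohort_config)
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "results"
    seed: int = 0
    replicates: int = 50

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 10_000 + STAGE_SEED_OFFSETS.get(stage, 99)) % (2**31 - 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_assoc(est, lo, hi, p):
    return f"{est:.4g} ({lo:.4g} to {hi:.4g}); p = {p:.3g}"


def cross_sectional_table(cohort: Cohort) -> pd.DataFrame:
    """Per-group adjusted mean volumes and WMH associations (ml/doubling)."""
    rows = []
    for name in cohort.subjects["group"].unique():
        sub = cohort.group(name).subjects
        for outcome in ("brain", "hippo"):
            fit = xs.fit_baseline_model(sub, outcome=outcome)
            rows.append({
                "group": name, "outcome": outcome, "n": fit.n,
                "adjusted_mean_ml": fit.adjusted_mean,
                "wmh_coef_ml_per_doubling": fit.coef("log2wmh"),
                "wmh_ci_low": fit.ci_low[fit.names.index("log2wmh")],
                "wmh_ci_high": fit.ci_high[fit.names.index("log2wmh")],
                "wmh_p": fit.p[fit.names.index("log2wmh")],
            })
    return pd.DataFrame(rows)


def longitudinal_tables(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """table3 (rates + WMH associations + adjusted), table4 (CSF subset),
    and the per-subject BLUP rates used for plotting."""
    t3_rows, t4_rows, blup_frames = [], [], []
    for name in cohort.subjects["group"].unique():
        grp = cohort.group(name)
        designs = {o: lg.build_design(grp.subjects, grp.observations, outcome=o)
                   for o in ("brain", "hippo")}
        fits = {o: lg.fit_rate_lmm(d) for o, d in designs.items()}
        joint = lg.fit_joint_lmm(designs["brain"], designs["hippo"])
        adj = {o: lg.adjusted_association(joint, target=o) for o in ("hippo", "brain")}
        for o in ("brain", "hippo"):
            f = fits[o]
            iw = f.names.index("log2wmh")
            a = adj[o]
            t3_rows.append({
                "group": name, "outcome": o, "n": f.n_subjects,
                "rate_ml_yr": f.coef("rate"),
                "rate_ci_low": f.ci_low[0], "rate_ci_high": f.ci_high[0],
                "wmh_coef_ml_yr_per_doubling": f.beta[iw],
                "wmh_ci_low": f.ci_low[iw], "wmh_ci_high": f.ci_high[iw],
                "wmh_p": f.p[iw],
                "wmh_adjusted_for_other_outcome": a.estimate,
                "adjusted_ci_low": a.ci_low, "adjusted_ci_high": a.ci_high,
                "adjusted_p": a.p,
            })

        # CSF-subset analysis, when the group has biomarker data
        n_csf = int(grp.subjects["csf_available"].sum())
        if n_csf >= 10:
            cj = lg.fit_with_csf(grp.subjects, grp.observations, joint=True)
            cadj = lg.adjusted_association(cj, target="hippo")
            for o, names, beta in (("brain", cj.names_brain, cj.beta_brain),
                                   ("hippo", cj.names_hippo, cj.beta_hippo)):
                se = cj.se_brain if o == "brain" else cj.se_hippo
                row = {"group": name, "outcome": o, "n": n_csf}
                for nm, label in (("rate", "rate_ml_yr"),
                                  ("log2wmh", "wmh_coef"),
                                  ("ab42_per10", "ab42_coef"),
                                  ("tau_per10", "tau_coef")):
                    i = names.index(nm)
                    row[label] = beta[i]
                    row[f"{label}_se"] = se[i]
                row["wmh_adjusted_for_brain"] = cadj.estimate if o == "hippo" else np.nan
                t4_rows.append(row)

        # covariate-free rates for the rate-vs-WMH plots
        for o in ("brain", "hippo"):
            plain = lg.build_design(grp.subjects, grp.observations, outcome=o,
                                    covariates=())
            b = lg.blup_rates(lg.fit_rate_lmm(plain))
            b.insert(1, "group", name)
            b.insert(2, "outcome", o)
            blup_frames.append(b)

    return (pd.DataFrame(t3_rows), pd.DataFrame(t4_rows),
            pd.concat(blup_frames, ignore_index=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    out = config.out_dir

    cohort: Cohort | None = None
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.cohort,
                                          seed=config.stage_seed("simulate"))
            cohort = generate_cohort(sim_cfg)
            spath, opath = write_cohort(cohort, out)
            manifest["stages"]["simulate"] = {"seed": sim_cfg.seed,
                                              "n_subjects": len(cohort.subjects),
                                              "n_observations": len(cohort.observations)}
            manifest["files"]["subjects.csv"] = _sha256(spath)
            manifest["files"]["observations.csv"] = _sha256(opath)
        elif any(s in config.stages for s in ("cross-sectional", "longitudinal", "plots")):
            stage = "load-inputs"
            from .cohort import read_cohort
            cohort = read_cohort(os.path.join(out, "subjects.csv"),
                                 os.path.join(out, "observations.csv"))

        if "cross-sectional" in config.stages:
            stage = "cross-sectional"
            t2 = cross_sectional_table(cohort)
            path = os.path.join(out, "table2.csv")
            t2.to_csv(path, index=False)
            manifest["files"]["table2.csv"] = _sha256(path)
            manifest["stages"]["cross-sectional"] = {"rows": len(t2)}

        if "longitudinal" in config.stages:
            stage = "longitudinal"
            t3, t4, blups = longitudinal_tables(cohort)
            for fname, frame in (("table3.csv", t3), ("table4.csv", t4),
                                 ("rates_blup.csv", blups)):
                path = os.path.join(out, fname)
                frame.to_csv(path, index=False)
                manifest["files"][fname] = _sha256(path)
            manifest["stages"]["longitudinal"] = {"rows": len(t3)}

        if "plots" in config.stages:
            stage = "plots"
            from .plots import plot_rates_vs_wmh
            blup_path = os.path.join(out, "rates_blup.csv")
            rates = pd.read_csv(blup_path)
            figs = plot_rates_vs_wmh(rates, cohort.subjects, out)
            for f in figs:
                manifest["files"][os.path.basename(f)] = _sha256(f)
            manifest["stages"]["plots"] = {"figures": [os.path.basename(f) for f in figs]}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def recovery_study(config: RunConfig, group_factory=None) -> pd.DataFrame:
    """Repeat generate + fit over ``config.replicates`` seeds.

    Reports the mean and SD across replicates of the main estimands
    (rates, WMH associations, adjusted associations) per group/outcome.
    """
    base = config.stage_seed("recovery")
    rows = []
    for r in range(config.replicates):
        sim_cfg = dataclasses.replace(config.cohort, seed=(base + r) % (2**31 - 1))
        cohort = generate_cohort(sim_cfg)
        t3, _, _ = longitudinal_tables(cohort)
        t3.insert(0, "replicate", r)
        rows.append(t3)
    all_rows = pd.concat(rows, ignore_index=True)
    est_cols = ["rate_ml_yr", "wmh_coef_ml_yr_per_doubling",
                "wmh_adjusted_for_other_outcome"]
    summary = (all_rows.groupby(["group", "outcome"])[est_cols]
               .agg(["mean", "std"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
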