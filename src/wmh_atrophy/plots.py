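"""Figure-style plots of predicted atrophy rates against WMH burden."""

from __future__ import annotations

import os
import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_rates_vs_wmh(rates: pd.DataFrame, subjects: pd.DataFrame,
                      out_dir: str) -> list[str]:
    """Per-group scatter of predicted rate vs log2WMH with an OLS line.

    One figure per outcome; the fitted slope/intercept per group are
    also written to ``rate_vs_wmh_lines.csv``.  Groups with fewer than
    3 points are skipped with a warning.
    """
    os.makedirs(out_dir, exist_ok=True)
    merged = rates.merge(subjects[["subject_id", "log2wmh"]], on="subject_id")
    paths = []
    line_rows = []
    for outcome in merged["outcome"].unique():
        sub = merged[merged["outcome"] == outcome]
        groups = [g for g in sub["group"].unique()]
        fig, axes = plt.subplots(1, max(len(groups), 1),
                                 figsize=(4 * max(len(groups), 1), 3.5),
                                 squeeze=False, sharey=True)
        plotted = False
        for ax, g in zip(axes[0], groups):
            d = sub[sub["group"] == g]
            if len(d) < 3:
                warnings.warn(f"group {g!r}/{outcome}: fewer than 3 points; skipped",
                              RuntimeWarning, stacklevel=2)
                ax.set_visible(False)
                continue
            x = d["log2wmh"].to_numpy()
            y = d["predicted_rate_ml_yr"].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            ax.scatter(x, y, s=8, alpha=0.5)
            xs = np.array([x.min(), x.max()])
            ax.plot(xs, intercept + slope * xs, color="crimson")
            ax.set_title(g)
            ax.set_xlabel("log2 WMH (ml)")
            line_rows.append({"group": g, "outcome": outcome,
                              "slope": slope, "intercept": intercept, "n": len(d)})
            plotted = True
        axes[0][0].set_ylabel(f"predicted {outcome} atrophy rate (ml/yr)")
        fig.tight_layout()
        if plotted:
            path = os.path.join(out_dir, f"rates_vs_wmh_{outcome}.png")
            fig.savefig(path, dpi=120)
            paths.append(path)
        plt.close(fig)
    if line_rows:
        lines_path = os.path.join(out_dir, "rate_vs_wmh_lines.csv")
        pd.DataFrame(line_rows).to_csv(lines_path, index=False)
        paths.append(lines_path)
    return paths
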