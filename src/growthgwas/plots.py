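"""Basic review plots: predicted BMI curves and a Manhattan plot.

These are working plots for human review of model fits and meta-analysis
output, not publication graphics.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .phenotypes import predict_trajectory

__all__ = ["save_curve_plot", "save_manhattan"]


def save_curve_plot(fits: dict, path, age_range=(0.0384, 17.0)) -> None:
    """Population-average BMI curves for one or more fitted models.

    ``fits`` maps a label (e.g. "male", "female" or a model label) to an
    LMMFit; curves are the fixed-effect predictions on the BMI scale.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, fit in fits.items():
        traj = predict_trajectory(fit, None, age_range=age_range)
        ax.plot(traj.ages, np.exp(traj.log_bmi), label=str(label))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("BMI (kg/m$^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_manhattan(meta, path, sig: float = 5e-8) -> None:
    """Manhattan plot of a summary-statistics table (chrom, pos, p)."""
    fig, ax = plt.subplots(figsize=(9, 3.5))
    offset = 0.0
    ticks, labels = [], []
    df = meta.copy()
    df["chrom_key"] = df["chrom"].astype(str)
    order = sorted(df["chrom_key"].unique(), key=lambda c: (len(c), c))
    for i, chrom in enumerate(order):
        sub = df[df["chrom_key"] == chrom].sort_values("pos")
        x = offset + (sub["pos"] - sub["pos"].min())
        ax.scatter(
            x, -np.log10(sub["p"].clip(lower=1e-300)),
            s=6, color="C0" if i % 2 == 0 else "C1",
        )
        ticks.append(float(x.mean()) if len(x) else offset)
        labels.append(chrom)
        offset = float(x.max()) + (sub["pos"].max() - sub["pos"].min() + 1) * 0.05 if len(x) else offset
    ax.axhline(-np.log10(sig), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
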