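"""Static diagnostic plots, rendered from already-written TSV reports.

Each function reads the corresponding report file so plot content is
guaranteed to match the tabular outputs; nothing here computes statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def forest_plot(estimates_tsv: str | Path, out_png: str | Path) -> Path:
    """Forest plot of every estimator's effect and 95% CI."""
    df = pd.read_csv(estimates_tsv, sep="\t")
    labels = [f"{r.exposure}→{r.outcome} [{r.method}]" for r in df.itertuples()]
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(df) + 1.5))
    ax.errorbar(
        df["beta"], y,
        xerr=[df["beta"] - df["ci_low"], df["ci_high"] - df["beta"]],
        fmt="s", color="black", ecolor="gray", capsize=3,
    )
    ax.axvline(0.0, color="firebrick", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("causal effect (log-odds per unit exposure)")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return Path(out_png)


def scatter_plot(
    instruments_tsv: str | Path, estimates_tsv: str | Path, out_png: str | Path
) -> Path:
    """Per-SNP effect scatter with one fitted line per estimator."""
    instr = pd.read_csv(instruments_tsv, sep="\t")
    ests = pd.read_csv(estimates_tsv, sep="\t")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(
        instr["beta_exp"], instr["beta_out"],
        xerr=instr["se_exp"], yerr=instr["se_out"],
        fmt="o", ms=3, color="steelblue", ecolor="lightsteelblue", lw=0.6,
    )
    xs = np.linspace(0, instr["beta_exp"].abs().max() * 1.05, 50)
    for row in ests.itertuples():
        intercept = 0.0 if pd.isna(getattr(row, "intercept", np.nan)) else row.intercept
        ax.plot(xs, intercept + row.beta * xs, label=row.method, lw=1.2)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return Path(out_png)


def funnel_plot(funnel_tsv: str | Path, out_png: str | Path, beta_ivw: float | None = None) -> Path:
    """Funnel of per-SNP ratio estimates against their precision."""
    df = pd.read_csv(funnel_tsv, sep="\t")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["ratio"], df["precision"], s=12, color="steelblue")
    if beta_ivw is not None:
        ax.axvline(beta_ivw, color="firebrick", lw=1.0, ls="--", label="IVW")
        ax.legend(fontsize=8)
    ax.set_xlabel("per-SNP Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return Path(out_png)


def leave_one_out_plot(loo_tsv: str | Path, out_png: str | Path) -> Path:
    """Leave-one-out IVW estimates, one row per omitted SNP."""
    df = pd.read_csv(loo_tsv, sep="\t")
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.18 * len(df) + 1.5))
    ax.errorbar(
        df["beta"], y, xerr=1.96 * df["se"],
        fmt="o", ms=2.5, color="black", ecolor="gray", lw=0.6,
    )
    ax.axvline(0.0, color="firebrick", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["rsid"], fontsize=5)
    ax.set_xlabel("IVW estimate omitting each SNP")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return Path(out_png)
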