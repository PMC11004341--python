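"""Sensitivity battery: Cochran's Q, Steiger filtering, MR-PRESSO,
leave-one-out and funnel data.

These diagnostics probe the instrumental-variable assumptions from different
angles: Q measures heterogeneity of the per-SNP ratio estimates (chi-square
with J−1 df under homogeneity), Steiger filtering discards variants that
explain more variance in the outcome than in the exposure (reverse
causation), MR-PRESSO detects pleiotropic outliers by comparing the observed
weighted residual sum of squares against a parametric simulation under the
no-pleiotropy null, and leave-one-out re-estimation flags single influential
variants. Funnel data (ratio vs precision) is emitted for plotting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientInstrumentsError
from .estimators import MREstimate, ivw
from .instruments import variance_explained


@dataclass
class HeterogeneityResult:
    """Cochran's Q with degrees of freedom and upper-tail chi-square p."""

    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class SteigerRecord:
    """Per-SNP directionality verdict: TRUE means exposure -> outcome."""

    rsid: str
    r2_exp: float
    r2_out: float
    direction_true: bool
    steiger_p: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_p: float
    outlier_p: np.ndarray
    outlier_indices: np.ndarray
    distortion_p: float
    beta_corrected: float
    n_sim: int


def _arrays(instruments: pd.DataFrame):
    return (
        instruments["beta_exp"].to_numpy(dtype=float),
        instruments["se_exp"].to_numpy(dtype=float),
        instruments["beta_out"].to_numpy(dtype=float),
        instruments["se_out"].to_numpy(dtype=float),
    )


def cochran_q(
    instruments: pd.DataFrame, beta_ivw: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios with weights (beta_exp/se_out)²."""
    bx, _, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    if beta_ivw is None:
        beta_ivw = ivw(instruments, "fixed", or_scale=False).beta
    q = float(np.sum(((by - beta_ivw * bx) / sy) ** 2))
    df = j - 1
    return HeterogeneityResult(q=q, df=df, pvalue=float(sps.chi2.sf(q, df)))


def steiger_table(
    instruments: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP Steiger directionality table.

    ``direction_true`` is r2_exp > r2_out; ``steiger_p`` is a two-sample
    Fisher-z test on the implied SNP-trait correlations with the respective
    cohort sizes (non-overlapping cohorts assumed).
    """
    df = instruments
    if "r2_exp" in df.columns:
        r2_exp = df["r2_exp"].to_numpy(dtype=float)
        r2_out = df["r2_out"].to_numpy(dtype=float)
    else:
        r2_exp = variance_explained(df["beta_exp"], df["se_exp"], df["n_exp"])
        r2_out = variance_explained(df["beta_out"], df["se_out"], df["n_out"])
    n_exp = df["n_exp"].to_numpy(dtype=float)
    n_out = df["n_out"].to_numpy(dtype=float)
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    se = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / se
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "rsid": df["rsid"].to_numpy(),
            "r2_exp": r2_exp,
            "r2_out": r2_out,
            "direction_true": r2_exp > r2_out,
            "steiger_p": p,
        }
    )


def steiger_filter(
    instruments: pd.DataFrame,
    alpha: float = 0.05,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard SNPs acting primarily on the outcome.

    Default rule: discard when ``direction_true`` is False *and* the Steiger
    p-value is below ``alpha`` (avoids discarding on sampling noise). With
    ``strict=True`` any FALSE direction is discarded regardless of p.
    Returns (retained instruments, per-SNP Steiger table with ``discarded``).
    """
    table = steiger_table(instruments)
    if strict:
        discard = ~table["direction_true"]
    else:
        discard = ~table["direction_true"] & (table["steiger_p"] < alpha)
    table = table.assign(discarded=discard)
    retained = instruments.loc[~discard.to_numpy()].reset_index(drop=True)
    return retained, table


def steiger_records(table: pd.DataFrame) -> list[SteigerRecord]:
    """Row-level dataclass view of a Steiger table."""
    return [
        SteigerRecord(
            rsid=row.rsid,
            r2_exp=float(row.r2_exp),
            r2_out=float(row.r2_out),
            direction_true=bool(row.direction_true),
            steiger_p=float(row.steiger_p),
        )
        for row in table.itertuples(index=False)
    ]


def _loo_ivw_terms(bx, by, sy):
    num = bx * by / sy**2
    den = bx**2 / sy**2
    beta_loo = (num.sum() - num) / (den.sum() - den)
    return beta_loo


def mr_presso(
    instruments: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test with outlier and distortion stages.

    The observed statistic is the weighted residual sum of squares of each
    SNP against the IVW fit with that SNP left out. The null distribution is
    simulated by redrawing both effect estimates from normal distributions at
    their standard errors around the leave-one-out predictions. Outliers are
    SNPs whose per-SNP residual exceeds its simulated distribution at the
    Bonferroni-corrected level; the distortion test compares the shift of the
    outlier-corrected IVW estimate against random removals of the same size.
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)

    w = 1.0 / sy**2
    beta_loo = _loo_ivw_terms(bx, by, sy)
    pred = beta_loo * bx
    obs_contrib = w * (by - pred) ** 2
    rss_obs = float(obs_contrib.sum())

    bxs = bx + sx * rng.standard_normal((n_sim, j))
    bys = pred + sy * rng.standard_normal((n_sim, j))
    num = bxs * bys / sy**2
    den = bxs**2 / sy**2
    beta_loo_s = (num.sum(axis=1, keepdims=True) - num) / (
        den.sum(axis=1, keepdims=True) - den
    )
    contrib_s = w * (bys - beta_loo_s * bxs) ** 2
    rss_s = contrib_s.sum(axis=1)

    global_p = float(np.mean(rss_s >= rss_obs))
    outlier_p = np.mean(contrib_s >= obs_contrib, axis=0)
    flagged = np.flatnonzero(outlier_p < outlier_alpha / j)

    beta_all = ivw(instruments, "fixed", or_scale=False).beta
    if flagged.size and flagged.size < j:
        keep = np.setdiff1d(np.arange(j), flagged)
        beta_corr = ivw(instruments.iloc[keep], "fixed", or_scale=False).beta
        d_obs = abs(beta_corr - beta_all)
        d_sim = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(j, size=flagged.size, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            d_sim[s] = (
                np.sum(bx[mask] * by[mask] / sy[mask] ** 2)
                / np.sum(bx[mask] ** 2 / sy[mask] ** 2)
                - beta_all
            )
        distortion_p = float(np.mean(np.abs(d_sim) >= d_obs))
    else:
        beta_corr = beta_all
        distortion_p = float("nan")

    return PressoResult(
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outlier_indices=flagged,
        distortion_p=distortion_p,
        beta_corrected=float(beta_corr),
        n_sim=n_sim,
    )


def leave_one_out(instruments: pd.DataFrame) -> pd.DataFrame:
    """IVW re-estimated with each instrument omitted in turn (J rows)."""
    bx, _, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 instruments")
    num = bx * by / sy**2
    den = bx**2 / sy**2
    beta = (num.sum() - num) / (den.sum() - den)
    se = (den.sum() - den) ** -0.5
    p = 2 * sps.norm.sf(np.abs(beta) / se)
    return pd.DataFrame(
        {"rsid": instruments["rsid"].to_numpy(), "beta": beta, "se": se, "pvalue": p}
    )


def funnel_data(
    instruments: pd.DataFrame, beta_ivw: float | None = None
) -> pd.DataFrame:
    """Per-SNP Wald ratio and precision (1/se_ratio) for funnel plotting."""
    bx, _, by, sy = _arrays(instruments)
    if len(bx) < 1:
        raise InsufficientInstrumentsError("funnel data needs >= 1 instrument")
    ratio = by / bx
    precision = np.abs(bx) / sy
    out = pd.DataFrame(
        {"rsid": instruments["rsid"].to_numpy(), "ratio": ratio, "precision": precision}
    )
    if beta_ivw is not None:
        out.attrs["beta_ivw"] = beta_ivw
    return out


@dataclass
class SensitivityReport:
    """Bundle of the sensitivity battery for one exposure -> outcome analysis."""

    heterogeneity: HeterogeneityResult | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso: PressoResult | None = None
    steiger: pd.DataFrame | None = None
    steiger_n_discarded: int = 0
    loo: pd.DataFrame | None = None
    funnel: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        het = self.heterogeneity
        return pd.DataFrame(
            [
                {
                    "q": het.q if het else np.nan,
                    "q_df": het.df if het else np.nan,
                    "q_p": het.pvalue if het else np.nan,
                    "egger_intercept": self.egger_intercept,
                    "egger_intercept_se": self.egger_intercept_se,
                    "egger_intercept_p": self.egger_intercept_p,
                    "presso_global_p": self.presso.global_p if self.presso else np.nan,
                    "presso_n_outliers": (
                        len(self.presso.outlier_indices) if self.presso else np.nan
                    ),
                    "steiger_n_discarded": self.steiger_n_discarded,
                }
            ]
        )


def sensitivity_battery(
    instruments: pd.DataFrame,
    egger_estimate: MREstimate | None = None,
    presso_n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> SensitivityReport:
    """Run every applicable diagnostic on an already Steiger-filtered frame."""
    report = SensitivityReport()
    j = len(instruments)
    if j >= 2:
        report.heterogeneity = cochran_q(instruments)
        report.loo = leave_one_out(instruments)
    if j >= 1:
        report.funnel = funnel_data(instruments)
    if egger_estimate is not None:
        report.egger_intercept = egger_estimate.intercept
        report.egger_intercept_se = egger_estimate.intercept_se
        report.egger_intercept_p = egger_estimate.intercept_p
    if j >= 4:
        report.presso = mr_presso(
            instruments, n_sim=presso_n_sim, outlier_alpha=outlier_alpha, seed=seed
        )
    else:
        report.warnings.append("presso_skipped_few_instruments")
    return report
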