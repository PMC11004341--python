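"""Causal-effect estimators for two-sample MR on harmonized instruments.

All estimators consume the instrument frame produced by harmonization
(columns ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out``; see
:mod:`mrchain.sumstats`). The battery mirrors standard practice:

* Wald ratio — single-SNP base case, first-order delta-method SE.
* IVW — inverse-variance-weighted meta-analysis of per-SNP ratios; the
  primary estimator. The random-effects variant scales the fixed SE by
  ``max(1, sqrt(Q/(J-1)))`` (multiplicative overdispersion).
* MR-Egger — weighted regression of outcome on exposure effects with a free
  intercept; a non-zero intercept signals directional pleiotropy.
  Instruments are first oriented so every exposure effect is non-negative.
* Weighted median — consistent when instruments carrying at least half the
  weight are valid; SE by seeded parametric bootstrap.
* Weighted mode — mode of the kernel-smoothed weighted ratio density,
  bandwidth a multiple of the weighted median absolute deviation.

95% intervals are normal-theory (estimate ± 1.96·SE) throughout; p-values
are two-sided normal except Egger, which uses the t distribution on J−2
degrees of freedom from its regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientInstrumentsError
from .sumstats import HarmonizedInstrument

Z95 = float(sps.norm.ppf(0.975))

METHODS = (
    "wald_ratio",
    "ivw_fixed",
    "ivw_random",
    "egger",
    "weighted_median",
    "weighted_mode",
)


@dataclass
class MREstimate:
    """One estimator's causal effect with normal-theory uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def _columns(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(instruments, pd.DataFrame):
        frame = instruments
    elif isinstance(instruments, HarmonizedInstrument):
        frame = pd.DataFrame([vars(instruments)])
    else:  # iterable of HarmonizedInstrument
        frame = pd.DataFrame([vars(r) for r in instruments])
    return (
        frame["beta_exp"].to_numpy(dtype=float),
        frame["se_exp"].to_numpy(dtype=float),
        frame["beta_out"].to_numpy(dtype=float),
        frame["se_out"].to_numpy(dtype=float),
    )


def _build(
    method: str,
    beta: float,
    se: float,
    n_snps: int,
    pvalue: float | None = None,
    or_scale: bool = True,
    **extra,
) -> MREstimate:
    ci_low, ci_high = beta - Z95 * se, beta + Z95 * se
    if pvalue is None:
        pvalue = 2 * sps.norm.sf(abs(beta) / se) if se > 0 else float(beta == 0.0)
    est = MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        pvalue=float(pvalue),
        n_snps=int(n_snps),
        **extra,
    )
    if or_scale:
        est.odds_ratio = math.exp(est.beta)
        est.or_ci_low = math.exp(est.ci_low)
        est.or_ci_high = math.exp(est.ci_high)
    return est


def wald_ratio(instrument, or_scale: bool = True) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    bx, _, by, sy = _columns(instrument)
    if len(bx) != 1:
        raise ValueError("wald_ratio takes exactly one instrument")
    bx, by, sy = float(bx[0]), float(by[0]), float(sy[0])
    if bx == 0:
        raise ValueError("undefined Wald ratio: beta_exp is zero")
    return _build("wald_ratio", by / bx, sy / abs(bx), 1, or_scale=or_scale)


def _q_statistic(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, beta: float) -> float:
    # Q = sum_j w_j (ratio_j - beta)^2 with w_j = (bx_j/sy_j)^2, rewritten to
    # avoid dividing by bx.
    return float(np.sum(((by - beta * bx) / sy) ** 2))


def ivw(instruments, mode: str = "fixed", or_scale: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (fixed or multiplicative random effects)."""
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be 'fixed' or 'random'")
    bx, _, by, sy = _columns(instruments)
    j = len(bx)
    if j < 1 or (mode == "random" and j < 2):
        raise InsufficientInstrumentsError(f"IVW ({mode}) needs >= {2 if mode == 'random' else 1} instruments")
    weights = (bx / sy) ** 2
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total IVW weight")
    if j == 1:
        # exact single-instrument reduction to the Wald ratio
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
    else:
        beta = float(np.sum(bx * by / sy**2) / total)
        se = float(total**-0.5)
    if mode == "random":
        q = _q_statistic(bx, by, sy, beta)
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return _build(f"ivw_{mode}", beta, se, j, or_scale=or_scale)


def egger(
    instruments,
    or_scale: bool = True,
    constrain_intercept: bool = False,
) -> MREstimate:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    ``constrain_intercept`` is a test hook: with the intercept pinned to zero
    the slope equals IVW computed with the same 1/se_out² weights.
    """
    bx, _, by, sy = _columns(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    # orient so every exposure effect is non-negative (Egger is not invariant
    # to allele orientation; this is the established convention)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2

    if constrain_intercept:
        slope = float(np.sum(w * x * y) / np.sum(w * x**2))
        resid = y - slope * x
        dof = j - 1
        sigma = math.sqrt(float(np.sum(w * resid**2)) / dof)
        se_slope = math.sqrt(1.0 / np.sum(w * x**2)) * max(1.0, sigma)
        p = 2 * sps.t.sf(abs(slope) / se_slope, dof)
        return _build("egger", slope, se_slope, j, pvalue=p, or_scale=or_scale)

    sw = w.sum()
    swx = np.sum(w * x)
    swy = np.sum(w * y)
    swxx = np.sum(w * x**2)
    swxy = np.sum(w * x * y)
    denom = sw * swxx - swx**2
    slope = float((sw * swxy - swx * swy) / denom)
    intercept = float((swy * swxx - swx * swxy) / denom)
    resid = y - intercept - slope * x
    dof = j - 2
    sigma = math.sqrt(float(np.sum(w * resid**2)) / dof)
    scale = max(1.0, sigma)
    se_slope = math.sqrt(sw / denom) * scale
    se_int = math.sqrt(swxx / denom) * scale
    p_slope = 2 * sps.t.sf(abs(slope) / se_slope, dof)
    p_int = 2 * sps.t.sf(abs(intercept) / se_int, dof)
    return _build(
        "egger",
        slope,
        se_slope,
        j,
        pvalue=p_slope,
        or_scale=or_scale,
        intercept=intercept,
        intercept_se=float(se_int),
        intercept_p=float(p_int),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        out[i] = np.interp(0.5, cum[i], v[i])
    return out


def _bootstrap_draws(
    bx, sx, by, sy, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    bxs = bx + sx * rng.standard_normal((n_boot, len(bx)))
    bys = by + sy * rng.standard_normal((n_boot, len(bx)))
    return bxs, bys


def weighted_median(
    instruments,
    n_boot: int = 1000,
    seed: int | None = None,
    or_scale: bool = True,
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios; bootstrap SE (seeded)."""
    bx, sx, by, sy = _columns(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bxs, bys = _bootstrap_draws(bx, sx, by, sy, n_boot, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = bys / bxs
        ws = (bxs / sy) ** 2
    boot = _weighted_median_rows(rs, ws)
    se = float(np.std(boot, ddof=1))
    return _build("weighted_median", beta, se, j, or_scale=or_scale)


def _kde_mode(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth: float,
    grid: np.ndarray,
) -> float:
    z = (grid[None, :] - ratios[:, None]) / bandwidth
    density = weights @ np.exp(-0.5 * z**2)
    return float(grid[int(np.argmax(density))])


def weighted_mode(
    instruments,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    or_scale: bool = True,
    grid_size: int = 256,
) -> MREstimate:
    """Mode of the smoothed weighted ratio density; bootstrap SE (seeded).

    Bandwidth = ``bandwidth_factor`` x weighted median absolute deviation of
    the ratios. If every ratio is identical the estimator degenerates to that
    ratio with SE 0.
    """
    bx, sx, by, sy = _columns(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted mode needs >= 3 instruments")
    ratios = by / bx
    weights = (bx / sy) ** 2
    weights = weights / weights.sum()

    wm = _weighted_median(ratios, weights)
    mad = _weighted_median(np.abs(ratios - wm), weights)
    h = bandwidth_factor * mad
    if h == 0:
        spread = float(np.std(ratios))
        if spread == 0:
            beta = float(ratios[0])
            p = 0.0 if beta != 0 else 1.0
            return _build("weighted_mode", beta, 0.0, j, pvalue=p, or_scale=or_scale)
        h = bandwidth_factor * spread

    lo = float(np.min(ratios)) - 3 * h
    hi = float(np.max(ratios)) + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    beta = _kde_mode(ratios, weights, h, grid)

    rng = np.random.default_rng(seed)
    modes = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e6 // (j * grid_size)) or 1))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        bxs, bys = _bootstrap_draws(bx, sx, by, sy, b, rng)
        with np.errstate(divide="ignore", invalid="ignore"):
            rs = bys / bxs
            ws = (bxs / sy) ** 2
        ws = ws / ws.sum(axis=1, keepdims=True)
        wms = _weighted_median_rows(rs, ws)
        mads = _weighted_median_rows(np.abs(rs - wms[:, None]), ws)
        hs = bandwidth_factor * mads
        hs[hs == 0] = h
        z = (grid[None, None, :] - rs[:, :, None]) / hs[:, None, None]
        dens = np.einsum("bj,bjg->bg", ws, np.exp(-0.5 * z**2))
        modes[done : done + b] = grid[np.argmax(dens, axis=1)]
        done += b
    se = float(np.std(modes, ddof=1))
    return _build("weighted_mode", beta, se, j, or_scale=or_scale)


def estimate_all(
    instruments,
    methods=METHODS,
    n_boot: int = 1000,
    seed: int | None = None,
    bandwidth_factor: float = 1.0,
    or_scale: bool = True,
) -> dict[str, MREstimate]:
    """Run every applicable estimator; skip those below their instrument minimum."""
    bx, _, _, _ = _columns(instruments)
    j = len(bx)
    out: dict[str, MREstimate] = {}
    for method in methods:
        if method == "wald_ratio" and j == 1:
            out[method] = wald_ratio(instruments, or_scale=or_scale)
        elif method == "ivw_fixed" and j >= 1:
            out[method] = ivw(instruments, "fixed", or_scale=or_scale)
        elif method == "ivw_random" and j >= 2:
            out[method] = ivw(instruments, "random", or_scale=or_scale)
        elif method == "egger" and j >= 3:
            out[method] = egger(instruments, or_scale=or_scale)
        elif method == "weighted_median" and j >= 3:
            out[method] = weighted_median(instruments, n_boot=n_boot, seed=seed, or_scale=or_scale)
        elif method == "weighted_mode" and j >= 3:
            out[method] = weighted_mode(
                instruments,
                bandwidth_factor=bandwidth_factor,
                n_boot=n_boot,
                seed=None if seed is None else seed + 1,
                or_scale=or_scale,
            )
    return out


ESTIMATE_TSV_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "intercept",
    "intercept_se",
    "intercept_p",
]


def estimates_to_frame(
    estimates: dict[str, MREstimate], exposure: str, outcome: str
) -> pd.DataFrame:
    rows = []
    for est in estimates.values():
        row = {"exposure": exposure, "outcome": outcome, **vars(est)}
        rows.append(row)
    return pd.DataFrame(rows, columns=ESTIMATE_TSV_COLUMNS)


def write_estimates(
    estimates: dict[str, MREstimate], path, exposure: str, outcome: str
) -> None:
    estimates_to_frame(estimates, exposure, outcome).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
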