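"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly at the summary level (no individual genotypes):
each SNP gets a true per-allele effect, and the observed effect is drawn
from ``Normal(true, se)`` with ``se = 1/sqrt(2*maf*(1-maf)*n)`` — the
standard large-sample standard error of a per-allele regression coefficient
at effective sample size ``n``. Binary traits live on the log-odds scale and
continuous traits in SD units under the same noise model.

The latent structure is an exposure -> mediator -> outcome chain: SNPs are
partitioned into exposure-causal, mediator-specific and null roles; the
mediator's true effect at each SNP is ``a * beta_exp + gamma`` (gamma the
mediator-specific component), and the outcome's is ``c' * beta_exp +
b * beta_med`` plus an optional pleiotropy term on a configurable fraction
of exposure instruments (balanced: zero-mean; directional: non-zero mean).
Block LD structure, palindromic variants and per-dataset allele swaps /
strand flips exercise clumping and harmonization. All randomness derives
from the single config seed; identical configs give bit-identical studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import derive_seed
from .exceptions import ConfigError
from .instruments import LDTable, write_ld_table
from .sumstats import CANONICAL_COLUMNS, SumStats, write_sumstats

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: minimum representable p-value written by the generator (avoids underflow
#: to exactly zero for extremely strong associations)
_P_FLOOR = 1e-320


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic study.

    Cohort sizes are *effective* sample sizes (for a binary trait,
    4/(1/cases + 1/controls)); the defaults emulate a large binary exposure
    GWAS (~42k effective), a small binary outcome GWAS (~6.3k effective) and
    a flow-cytometry-scale continuous trait cohort (~3.8k), with chain
    effects a = 0.3 SD per log-odds, b = 0.25 log-odds per SD and direct
    effect c' = 0.065 (implied mediated proportion 53.6%).
    """

    n_snps: int = 600
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 42_000
    n_out: int = 6_270
    n_med: int = 3_757
    true_a: float = 0.3
    true_b: float = 0.25
    true_c_prime: float = 0.065
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    invalid_fraction: float = 0.0
    ld_block_size: int = 5
    ld_within_r2: float = 0.3
    palindromic_fraction: float = 0.15
    exposure_causal_fraction: float = 0.3
    mediator_causal_fraction: float = 0.3
    effect_sd_exp: float = 0.035
    effect_sd_med: float = 0.4
    allele_swap_fraction: float = 0.3
    strand_flip_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "invalid_fraction",
            "palindromic_fraction",
            "exposure_causal_fraction",
            "mediator_causal_fraction",
            "allele_swap_fraction",
            "strand_flip_fraction",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_exp", "n_out", "n_med"):
            if getattr(self, name) <= 2:
                raise ConfigError(f"{name} must exceed 2")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be positive")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError("pleiotropy_mode must be none|balanced|directional")
        if not 0 <= self.ld_within_r2 <= 1:
            raise ConfigError("ld_within_r2 must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class StudyTruth:
    """Generating parameters recorded for test harnesses."""

    a: float
    b: float
    c_prime: float
    roles: np.ndarray
    beta_exp_true: np.ndarray
    beta_med_true: np.ndarray
    beta_out_true: np.ndarray
    pleiotropy: np.ndarray

    @property
    def c(self) -> float:
        """Implied total exposure -> outcome effect a*b + c'."""
        return self.a * self.b + self.c_prime

    @property
    def proportion(self) -> float:
        """Implied mediated proportion (a*b)/(a*b + c')."""
        return (self.a * self.b) / self.c

    def summary_dict(self) -> dict:
        roles, counts = np.unique(self.roles, return_counts=True)
        return {
            "a": self.a,
            "b": self.b,
            "c_prime": self.c_prime,
            "c": self.c,
            "proportion_pct": 100.0 * self.proportion,
            "role_counts": dict(zip(roles.tolist(), counts.tolist())),
            "n_pleiotropic": int(np.count_nonzero(self.pleiotropy)),
        }


@dataclass
class SyntheticStudy:
    exposure: SumStats
    mediator: SumStats
    outcome: SumStats
    ld: LDTable
    truth: StudyTruth


@dataclass
class _Panel:
    """Shared SNP panel: everything that is common across cohorts."""

    rsid: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    roles: np.ndarray
    beta_exp_true: np.ndarray
    gamma_med: np.ndarray
    pleiotropy: np.ndarray
    block: np.ndarray


def _build_panel(config: SimulationConfig) -> _Panel:
    rng = np.random.default_rng(derive_seed(config.seed, "panel"))
    m = config.n_snps
    rsid = np.array([f"rs{100000 + i}" for i in range(m)])
    block = np.arange(m) // config.ld_block_size
    chrom = ((block % 22) + 1).astype(str)
    ordinal = block // 22  # ordinal of the block on its chromosome
    pos = 1 + ordinal * 2_000_000 + (np.arange(m) % config.ld_block_size) * 10_000

    maf = rng.uniform(*config.maf_range, m)
    pal = rng.random(m) < config.palindromic_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), m)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), m)
    ea = np.where(
        pal,
        np.array([p[0] for p in _PALINDROMIC_PAIRS])[pal_idx],
        np.array([p[0] for p in _NONPALINDROMIC_PAIRS])[non_idx],
    )
    oa = np.where(
        pal,
        np.array([p[1] for p in _PALINDROMIC_PAIRS])[pal_idx],
        np.array([p[1] for p in _NONPALINDROMIC_PAIRS])[non_idx],
    )

    draw = rng.random(m)
    roles = np.where(
        draw < config.exposure_causal_fraction,
        "exposure",
        np.where(
            draw < config.exposure_causal_fraction + config.mediator_causal_fraction,
            "mediator",
            "null",
        ),
    )
    beta_exp_true = np.where(
        roles == "exposure", rng.normal(0.0, config.effect_sd_exp, m), 0.0
    )
    gamma_med = np.where(
        roles == "mediator", rng.normal(0.0, config.effect_sd_med, m), 0.0
    )

    pleiotropy = np.zeros(m)
    if config.pleiotropy_mode != "none" and config.invalid_fraction > 0:
        exp_idx = np.flatnonzero(roles == "exposure")
        n_invalid = int(round(config.invalid_fraction * len(exp_idx)))
        invalid = rng.choice(exp_idx, size=n_invalid, replace=False)
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        pleiotropy[invalid] = rng.normal(mean, config.pleiotropy_sd, n_invalid)

    return _Panel(
        rsid=rsid, chrom=chrom, pos=pos, maf=maf, ea=ea, oa=oa, roles=roles,
        beta_exp_true=beta_exp_true, gamma_med=gamma_med, pleiotropy=pleiotropy,
        block=block,
    )


def sampling_se(maf, n):
    """Per-allele standard error 1/sqrt(2*maf*(1-maf)*n)."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * float(n))


def _observe(true_beta, maf, n, rng):
    se = sampling_se(maf, n)
    beta = true_beta + se * rng.standard_normal(len(se))
    p = np.clip(2 * sps.norm.sf(np.abs(beta) / se), _P_FLOOR, 1.0)
    return beta, se, p


def _dataset(panel: _Panel, true_beta, n, rng, trait) -> SumStats:
    beta, se, p = _observe(true_beta, panel.maf, n, rng)
    ea, oa, eaf = panel.ea, panel.oa, panel.maf
    frame = pd.DataFrame(
        {
            "rsid": panel.rsid,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": np.full(len(beta), int(n), dtype=np.int64),
        }
    )
    return SumStats(frame[CANONICAL_COLUMNS], trait=trait)


def _apply_presentation(
    stats: SumStats, rng: np.random.Generator, swap_fraction: float, flip_fraction: float
) -> SumStats:
    """Randomly swap effect/other alleles (negating beta) and strand-flip.

    Emulates datasets reported on different strands / allele orderings so the
    harmonization step has real work to do; the represented association is
    unchanged.
    """
    df = stats.frame.copy()
    m = len(df)
    swap = rng.random(m) < swap_fraction
    flip = rng.random(m) < flip_fraction
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    ea_s = np.where(swap, oa, ea)
    oa_s = np.where(swap, ea, oa)
    comp = np.vectorize(_COMPLEMENT.get)
    ea_f = np.where(flip, comp(ea_s), ea_s)
    oa_f = np.where(flip, comp(oa_s), oa_s)
    df["effect_allele"] = ea_f
    df["other_allele"] = oa_f
    df["beta"] = np.where(swap, -df["beta"], df["beta"])
    df["eaf"] = np.where(swap, 1.0 - df["eaf"], df["eaf"])
    return SumStats(df, trait=stats.trait)


def _ld_table(panel: _Panel, config: SimulationConfig) -> LDTable:
    table = LDTable()
    if config.ld_block_size < 2 or config.ld_within_r2 <= 0:
        return table
    for b in np.unique(panel.block):
        members = panel.rsid[panel.block == b]
        for i in range(len(members)):
            for k in range(i + 1, len(members)):
                table.set(members[i], members[k], config.ld_within_r2)
    return table


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate exposure, mediator and outcome summary statistics plus LD.

    Cohorts are non-overlapping by construction (independent noise draws),
    matching the two-sample assumption. Identical configs give bit-identical
    output.
    """
    panel = _build_panel(config)
    beta_med_true = config.true_a * panel.beta_exp_true + panel.gamma_med
    beta_out_true = (
        config.true_c_prime * panel.beta_exp_true
        + config.true_b * beta_med_true
        + panel.pleiotropy
    )

    exposure = _dataset(
        panel, panel.beta_exp_true, config.n_exp,
        np.random.default_rng(derive_seed(config.seed, "exposure")), "exposure",
    )
    mediator = _dataset(
        panel, beta_med_true, config.n_med,
        np.random.default_rng(derive_seed(config.seed, "mediator")), "mediator",
    )
    outcome = _dataset(
        panel, beta_out_true, config.n_out,
        np.random.default_rng(derive_seed(config.seed, "outcome")), "outcome",
    )
    mediator = _apply_presentation(
        mediator,
        np.random.default_rng(derive_seed(config.seed, "mediator-presentation")),
        config.allele_swap_fraction, config.strand_flip_fraction,
    )
    outcome = _apply_presentation(
        outcome,
        np.random.default_rng(derive_seed(config.seed, "outcome-presentation")),
        config.allele_swap_fraction, config.strand_flip_fraction,
    )

    truth = StudyTruth(
        a=config.true_a, b=config.true_b, c_prime=config.true_c_prime,
        roles=panel.roles, beta_exp_true=panel.beta_exp_true,
        beta_med_true=beta_med_true, beta_out_true=beta_out_true,
        pleiotropy=panel.pleiotropy,
    )
    return SyntheticStudy(
        exposure=exposure, mediator=mediator, outcome=outcome,
        ld=_ld_table(panel, config), truth=truth,
    )


def simulate_null_trait(
    config: SimulationConfig, seed: int, n: int | None = None, trait: str = "null_trait"
) -> SumStats:
    """A trait with its own genetics but no causal link to exposure or outcome.

    Causal SNPs are drawn from the panel's null-role pool (so they are
    disjoint from exposure and mediator instruments) with the mediator's
    causal fraction and effect scale. Used for false-positive-rate checks of
    the screen.
    """
    panel = _build_panel(config)
    rng = np.random.default_rng(seed)
    pool = panel.roles == "null"
    causal = pool & (rng.random(config.n_snps) < config.mediator_causal_fraction)
    true_beta = np.where(causal, rng.normal(0.0, config.effect_sd_med, config.n_snps), 0.0)
    stats = _dataset(panel, true_beta, n or config.n_med, rng, trait)
    return _apply_presentation(
        stats, rng, config.allele_swap_fraction, config.strand_flip_fraction
    )


def simulate_benchmark(
    config: SimulationConfig, n_null_traits: int, seed: int | None = None
) -> tuple[SyntheticStudy, dict[str, SumStats]]:
    """A full screening benchmark: one chain study plus null candidate traits.

    Returns the study and a trait dictionary containing the true mediator
    (under trait id ``"mediator"``) and ``n_null_traits`` null traits.
    """
    seed = config.seed if seed is None else seed
    study = simulate_study(config)
    traits: dict[str, SumStats] = {"mediator": study.mediator}
    for i in range(n_null_traits):
        trait_id = f"null_{i:03d}"
        traits[trait_id] = simulate_null_trait(
            config, derive_seed(seed, f"null:{i}"), trait=trait_id
        )
    return study, traits


def simulate_instruments(
    j: int,
    theta: float = 0.14,
    seed: int | None = 0,
    se_exp: float = 0.002,
    se_out: float = 0.005,
    bx_range: tuple[float, float] = (0.02, 0.15),
    pleiotropy_mode: str = "none",
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    invalid_fraction: float = 1.0,
    n_exp: int = 100_000,
    n_out: int = 100_000,
) -> tuple[pd.DataFrame, dict]:
    """Directly simulate a harmonized instrument frame with true effect theta.

    Bypasses the GWAS layer: true exposure effects are uniform on
    ``bx_range`` (all positive — pleiotropy is defined on this oriented
    scale), observed effects get normal noise at the stated SEs. Returns the
    instrument frame and the generating truth.
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*bx_range, j)
    alpha = np.zeros(j)
    if pleiotropy_mode != "none":
        invalid = rng.random(j) < invalid_fraction
        mean = pleiotropy_mean if pleiotropy_mode == "directional" else 0.0
        alpha[invalid] = rng.normal(mean, pleiotropy_sd, int(invalid.sum()))
    by_true = theta * bx_true + alpha
    bx = bx_true + se_exp * rng.standard_normal(j)
    by = by_true + se_out * rng.standard_normal(j)
    frame = pd.DataFrame(
        {
            "rsid": [f"iv{i}" for i in range(j)],
            "beta_exp": bx,
            "se_exp": se_exp,
            "p_exp": np.clip(2 * sps.norm.sf(np.abs(bx) / se_exp), _P_FLOOR, 1.0),
            "n_exp": n_exp,
            "beta_out": by,
            "se_out": se_out,
            "p_out": np.clip(2 * sps.norm.sf(np.abs(by) / se_out), _P_FLOOR, 1.0),
            "n_out": n_out,
        }
    )
    truth = {"theta": theta, "pleiotropy": alpha, "beta_exp_true": bx_true}
    return frame, truth


def simulate_reverse_causation(
    n_snps: int = 400,
    rho: float = 0.5,
    n_exp: int = 100_000,
    n_out: int = 100_000,
    effect_sd: float = 0.05,
    maf: float = 0.3,
    p_threshold: float = 5e-5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Instruments under reverse causation: SNPs act on the outcome trait.

    Every SNP's true effect is on the *outcome*; the exposure association is
    induced with attenuation ``rho`` (outcome -> exposure effect). The
    returned frame contains the SNPs that would be (wrongly) selected as
    exposure instruments at ``p_threshold`` — the population Steiger
    filtering should discard.
    """
    rng = np.random.default_rng(seed)
    g_out = rng.normal(0.0, effect_sd, n_snps)
    g_exp = rho * g_out
    se_e = float(sampling_se(maf, n_exp))
    se_o = float(sampling_se(maf, n_out))
    bx = g_exp + se_e * rng.standard_normal(n_snps)
    by = g_out + se_o * rng.standard_normal(n_snps)
    p_exp = np.clip(2 * sps.norm.sf(np.abs(bx) / se_e), _P_FLOOR, 1.0)
    p_out = np.clip(2 * sps.norm.sf(np.abs(by) / se_o), _P_FLOOR, 1.0)
    frame = pd.DataFrame(
        {
            "rsid": [f"rv{i}" for i in range(n_snps)],
            "beta_exp": bx,
            "se_exp": se_e,
            "p_exp": p_exp,
            "n_exp": n_exp,
            "beta_out": by,
            "se_out": se_o,
            "p_out": p_out,
            "n_out": n_out,
        }
    )
    return frame.loc[frame["p_exp"] < p_threshold].reset_index(drop=True)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study in the pipeline's own TSV formats plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "mediator": outdir / "mediator.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "truth": outdir / "truth.json",
    }
    write_sumstats(study.exposure, paths["exposure"])
    write_sumstats(study.mediator, paths["mediator"])
    write_sumstats(study.outcome, paths["outcome"])
    write_ld_table(study.ld, paths["ld"])
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth.summary_dict(), fh, indent=2)
    return paths
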