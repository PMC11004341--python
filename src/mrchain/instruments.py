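"""Instrument selection: p-value threshold, greedy LD clumping, strength filters.

Selection follows the standard two-sample MR recipe: keep SNPs associated
with the exposure below a p-value threshold (default 5e-5), prune them to
approximate linkage equilibrium by greedy clumping (10,000 kb window,
r-squared < 0.001 by default), drop palindromic variants, and discard weak
instruments with F < 10. The LD reference is an input table of pairwise
r-squared values; pairs absent from the table are treated as unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .sumstats import PALINDROMIC, SumStats, harmonize_frames


@dataclass
class SelectionConfig:
    """Thresholds for instrument selection.

    p_threshold : inclusion p-value cutoff for exposure association.
    clump_r2 : maximum pairwise LD r-squared between retained SNPs.
    clump_window_kb : physical window (kilobases) within which LD is pruned.
    f_min : minimum per-SNP instrument-strength F statistic.
    """

    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ConfigError("clump_window_kb must be positive")
        if self.f_min < 0:
            raise ConfigError("f_min must be non-negative")


class LDTable:
    """Symmetric pairwise r-squared lookup; absent pairs count as r² = 0."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.set(a, b, float(r2))

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LDTable":
        table = cls()
        for a, b, r2 in zip(frame["rsid_a"], frame["rsid_b"], frame["r2"]):
            table.set(str(a), str(b), float(r2))
        return table

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])


def read_ld_table(path: str | Path) -> LDTable:
    """Read a TSV LD table with header ``rsid_a rsid_b r2``."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("rsid_a", "rsid_b", "r2") if c not in frame.columns]
    if missing:
        raise ConfigError(f"LD table {path}: missing columns {missing}")
    return LDTable.from_frame(frame)


def write_ld_table(table: LDTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def filter_by_pvalue(stats: SumStats, p_threshold: float) -> SumStats:
    """Retain exactly the records with pvalue < threshold, order preserved."""
    return stats.subset(stats.frame["pvalue"] < p_threshold)


def f_statistic(beta_exp, se_exp):
    """Single-SNP instrument-strength F = (beta/se)²."""
    beta = np.asarray(beta_exp, dtype=float)
    se = np.asarray(se_exp, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se_exp must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out

def variance_explained(beta, se, n):
    """Variance in a trait explained by one SNP, z-score approximation.

    r² = z² / (z² + n) with z = beta/se; the standard summary-data
    approximation to the squared SNP-trait correlation, valid for both
    continuous and (approximately) binary traits.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    z2 = (beta / se) ** 2
    out = z2 / (z2 + n)
    return float(out) if out.ndim == 0 else out


def clump(
    stats: SumStats,
    ld: LDTable | None,
    config: SelectionConfig,
) -> tuple[SumStats, pd.DataFrame]:
    """Greedy LD clumping of candidate instruments.

    Candidates are ranked by ascending p-value (ties broken by rsid so the
    result is independent of input order). The best remaining SNP is accepted
    and every remaining SNP on the same chromosome within the window whose
    r² with it is >= ``clump_r2`` is discarded. Returns the retained subset
    sorted by (chrom, pos) and a per-SNP disposition report.
    """
    ld = ld or LDTable()
    df = stats.frame
    order = df.sort_values(["pvalue", "rsid"], kind="mergesort").reset_index(drop=True)
    rsids = order["rsid"].to_numpy()
    chroms = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy(dtype=np.int64)
    window_bp = int(config.clump_window_kb * 1000)

    m = len(order)
    rank = {r: i for i, r in enumerate(rsids)}
    # sparse adjacency: only pairs recorded in the LD table can be clumped
    neighbours: dict[int, list[tuple[int, float]]] = {}
    for (a, b), r2 in ld._r2.items():
        ia, ib = rank.get(a), rank.get(b)
        if ia is None or ib is None or r2 < config.clump_r2:
            continue
        neighbours.setdefault(ia, []).append((ib, r2))
        neighbours.setdefault(ib, []).append((ia, r2))

    removed = np.zeros(m, dtype=bool)
    disposition = np.empty(m, dtype=object)
    accepted: list[str] = []
    for i in range(m):
        if removed[i]:
            continue
        disposition[i] = "retained"
        accepted.append(rsids[i])
        for j, _ in neighbours.get(i, ()):
            if (
                j > i
                and not removed[j]
                and chroms[j] == chroms[i]
                and abs(int(pos[j]) - int(pos[i])) <= window_bp
            ):
                removed[j] = True
                disposition[j] = f"clumped_to:{rsids[i]}"

    report = pd.DataFrame({"rsid": rsids, "disposition": disposition})
    keep = df["rsid"].isin(accepted)
    retained = (
        df.loc[keep]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SumStats(retained, trait=stats.trait), report


def _palindromic_mask(frame: pd.DataFrame) -> pd.Series:
    pair = frame["effect_allele"] + frame["other_allele"]
    return pair.isin(["AT", "TA", "CG", "GC"])


def select_instruments(
    exposure: SumStats,
    outcome: SumStats,
    ld: LDTable | None = None,
    config: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full instrument-selection pipeline for one exposure/outcome pair.

    Steps: p-value filter -> palindrome exclusion -> LD clumping -> F filter
    -> harmonization against the outcome. Returns the harmonized instrument
    frame (with ``f_stat``, ``r2_exp``, ``r2_out`` columns) and a per-SNP
    disposition report (``retained``, ``p_fail``, ``palindromic``,
    ``ambiguous``, ``clumped_to:<rsid>``, ``weak_F``, ``absent_in_outcome``).
    """
    config = config or SelectionConfig()
    dispositions: list[pd.DataFrame] = []

    df = exposure.frame
    sig = df["pvalue"] < config.p_threshold
    if (~sig).any():
        dispositions.append(
            pd.DataFrame({"rsid": df.loc[~sig, "rsid"], "disposition": "p_fail"})
        )
    df = df.loc[sig]

    pal = _palindromic_mask(df)
    if pal.any():
        dispositions.append(
            pd.DataFrame({"rsid": df.loc[pal, "rsid"], "disposition": PALINDROMIC})
        )
    df = df.loc[~pal]

    clumped, clump_report = clump(SumStats(df.reset_index(drop=True)), ld, config)
    dispositions.append(
        clump_report.loc[clump_report["disposition"] != "retained"]
    )
    df = clumped.frame

    f = (df["beta"] / df["se"]) ** 2
    weak = f < config.f_min
    if weak.any():
        dispositions.append(
            pd.DataFrame({"rsid": df.loc[weak, "rsid"], "disposition": "weak_F"})
        )
    df = df.loc[~weak]

    instr, exclusions = harmonize_frames(df.reset_index(drop=True), outcome.frame)
    if len(exclusions):
        dispositions.append(
            exclusions.rename(columns={"reason": "disposition"})
        )

    instr = instr.assign(
        f_stat=(instr["beta_exp"] / instr["se_exp"]) ** 2,
        r2_exp=variance_explained(instr["beta_exp"], instr["se_exp"], instr["n_exp"]),
        r2_out=variance_explained(instr["beta_out"], instr["se_out"], instr["n_out"]),
    )
    dispositions.append(
        pd.DataFrame({"rsid": instr["rsid"], "disposition": "retained"})
    )
    report = pd.concat(dispositions, ignore_index=True)
    return instr, report
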