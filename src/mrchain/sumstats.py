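"""GWAS summary-statistic containers, I/O and allele harmonization.

Canonical on-disk format is a tab-separated file with header
``rsid chrom pos effect_allele other_allele eaf beta se pvalue n`` and ``NA``
for missing values. Positions are 1-based. Betas are log-odds for binary
traits and SD units for continuous traits; ``se`` is the standard error of
``beta`` and must be positive.

Harmonization aligns an exposure/outcome SNP pair onto the exposure's effect
allele, flipping the outcome effect sign when the alleles are swapped and
resolving strand flips via base complements. Palindromic (A/T, C/G) pairs are
excluded unconditionally — no frequency-based strand inference is attempted —
and indels or irreconcilable allele pairs are tagged ``ambiguous``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]
#: columns that must be present and non-missing in every record
MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "eaf"]

VALID_BASES = frozenset("ACGT")
_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")

#: harmonization exclusion tags (data, not exceptions)
PALINDROMIC = "palindromic"
AMBIGUOUS = "ambiguous"
ABSENT_IN_OUTCOME = "absent_in_outcome"


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome SNP pair aligned to a shared effect allele."""

    rsid: str
    chrom: str
    pos: int
    beta_exp: float
    se_exp: float
    p_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    p_out: float
    n_out: int
    eaf_exp: float | None
    flipped: bool


@dataclass
class DropReport:
    """Counts of rows dropped during validation, keyed by reason."""

    counts: dict[str, int] = field(default_factory=dict)
    rsids: dict[str, list[str]] = field(default_factory=dict)

    def add(self, reason: str, rsid_values) -> None:
        ids = list(rsid_values)
        if not ids:
            return
        self.counts[reason] = self.counts.get(reason, 0) + len(ids)
        self.rsids.setdefault(reason, []).extend(ids)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class SumStats:
    """An ordered, validated collection of summary-statistic records.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    columns; bulk pipeline operations work on ``.frame`` directly while
    ``records()`` exposes the row-level dataclass view.
    """

    def __init__(self, frame: pd.DataFrame, trait: str = "trait"):
        missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"summary statistics missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.trait = trait

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SumStats(trait={self.trait!r}, n_snps={len(self)})"

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, trait: str = "trait"
    ) -> tuple["SumStats", DropReport]:
        clean, report = validate_frame(frame)
        return cls(clean, trait=trait), report

    @classmethod
    def from_records(
        cls, records, trait: str = "trait"
    ) -> "SumStats":
        frame = pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])
        return cls(frame[CANONICAL_COLUMNS], trait=trait)

    def records(self) -> Iterator[SummaryStatRecord]:
        for row in self.frame.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            yield SummaryStatRecord(
                rsid=row.rsid,
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=eaf,
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=int(row.n),
            )

    def subset(self, mask) -> "SumStats":
        return SumStats(self.frame.loc[mask].reset_index(drop=True), trait=self.trait)


class ReadResult(NamedTuple):
    stats: SumStats
    report: DropReport


def validate_frame(frame: pd.DataFrame) -> tuple[pd.DataFrame, DropReport]:
    """Validate rows, dropping and counting failures; order is preserved.

    Duplicate rsids keep the smallest-p row (ties by file order); the rest are
    counted under ``duplicate_rsid``.
    """
    report = DropReport()
    df = frame.copy()
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"missing mandatory column {col!r}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[CANONICAL_COLUMNS]

    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    alleles = df["effect_allele"].astype(str).str.upper()
    others = df["other_allele"].astype(str).str.upper()
    df["effect_allele"] = alleles
    df["other_allele"] = others

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        mask = mask.fillna(False) if mask.dtype == object else mask
        if mask.any():
            report.add(reason, df.loc[mask, "rsid"])
            df = df.loc[~mask]

    drop(
        df[["pos", "beta", "se", "pvalue", "n"]].isna().any(axis=1)
        | df["rsid"].isin(["", "nan"])
        | df["effect_allele"].isin(["", "NAN", "NA"])
        | df["other_allele"].isin(["", "NAN", "NA"]),
        "missing_field",
    )
    bad_allele = ~df["effect_allele"].str.fullmatch("[ACGT]+") | ~df[
        "other_allele"
    ].str.fullmatch("[ACGT]+")
    drop(bad_allele, "invalid_allele")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(df["se"] <= 0, "nonpositive_se")
    drop((df["pvalue"] <= 0) | (df["pvalue"] > 1), "invalid_pvalue")
    drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "invalid_eaf")
    drop(df["pos"] < 1, "invalid_position")
    drop(df["n"] <= 0, "invalid_n")

    if df["rsid"].duplicated().any():
        # keep the smallest-p row per rsid, stable in file order
        order = df.assign(_row=np.arange(len(df)))
        keep_idx = (
            order.sort_values(["pvalue", "_row"], kind="mergesort")
            .drop_duplicates("rsid")
            .index
        )
        dup_mask = ~df.index.isin(keep_idx)
        report.add("duplicate_rsid", df.loc[dup_mask, "rsid"])
        df = df.loc[~dup_mask]

    df = df.astype({"pos": np.int64, "n": np.int64})
    return df.reset_index(drop=True), report


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str | None = None,
) -> ReadResult:
    """Read a summary-statistics TSV into validated records.

    ``column_map`` maps file headers to canonical field names so exports with
    arbitrary headers can be ingested. Rows failing validation are dropped and
    counted in the returned report.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    except OSError:
        raise
    except Exception as exc:  # malformed file content
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory columns {missing}")
    stats, report = SumStats.from_frame(raw, trait=trait or path.stem)
    return ReadResult(stats, report)


def write_sumstats(stats: SumStats, path: str | Path) -> None:
    """Write records in the canonical TSV format (missing values as NA)."""
    stats.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True exactly when the allele pair is {A,T} or {C,G}."""
    for allele in (effect_allele, other_allele):
        if allele not in VALID_BASES:
            raise ValueError(f"allele {allele!r} not a single nucleotide in ACGT")
    pair = {effect_allele, other_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


def complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT_TABLE)


def harmonize(
    exposure: SummaryStatRecord, outcome: SummaryStatRecord
) -> Union[HarmonizedInstrument, str]:
    """Align one exposure/outcome pair onto the exposure's effect allele.

    Returns a :class:`HarmonizedInstrument`, or an exclusion tag string
    (``"palindromic"`` or ``"ambiguous"``). Tags are data, not exceptions.
    """
    if exposure.rsid != outcome.rsid:
        raise ValueError("harmonize requires records for the same rsid")
    ea, oa = exposure.effect_allele, exposure.other_allele
    eb, ob = outcome.effect_allele, outcome.other_allele
    if max(len(a) for a in (ea, oa, eb, ob)) > 1:
        return AMBIGUOUS
    if is_palindromic(ea, oa) or is_palindromic(eb, ob):
        return PALINDROMIC

    if (eb, ob) == (ea, oa) or (eb, ob) == (complement(ea), complement(oa)):
        flipped = False
        beta_out = outcome.beta
    elif (eb, ob) == (oa, ea) or (eb, ob) == (complement(oa), complement(ea)):
        flipped = True
        beta_out = -outcome.beta
    else:
        return AMBIGUOUS
    return HarmonizedInstrument(
        rsid=exposure.rsid,
        chrom=exposure.chrom,
        pos=exposure.pos,
        beta_exp=exposure.beta,
        se_exp=exposure.se,
        p_exp=exposure.pvalue,
        n_exp=exposure.n,
        beta_out=beta_out,
        se_out=outcome.se,
        p_out=outcome.pvalue,
        n_out=outcome.n,
        eaf_exp=exposure.eaf,
        flipped=flipped,
    )


INSTRUMENT_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "beta_exp",
    "se_exp",
    "p_exp",
    "n_exp",
    "beta_out",
    "se_out",
    "p_out",
    "n_out",
    "eaf_exp",
    "flipped",
]


def _allele_codes(alleles: np.ndarray) -> np.ndarray:
    """Map single-base alleles to codes A=0, C=1, G=2, T=3; anything else -1.

    The complement of a valid code is ``3 - code``, and a (distinct) pair is
    palindromic exactly when its codes sum to 3.
    """
    codes = np.full(len(alleles), -1, dtype=np.int8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        codes[alleles == base] = code
    return codes


def harmonize_frames(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised harmonization of two summary-statistic frames.

    Returns ``(instruments, exclusions)`` where ``instruments`` has the
    :data:`INSTRUMENT_COLUMNS` layout and ``exclusions`` is a
    ``rsid``/``reason`` frame covering palindromic, ambiguous and
    absent-in-outcome SNPs. Exposure SNPs absent from the outcome dataset are
    dropped (no proxy lookup) and reported.
    """
    exp_rsid = exposure["rsid"].to_numpy()
    out_index = pd.Index(outcome["rsid"])
    loc = out_index.get_indexer(exp_rsid)
    reasons = np.empty(len(exp_rsid), dtype=object)
    present = loc >= 0
    reasons[~present] = ABSENT_IN_OUTCOME

    exp = exposure.loc[present]
    out = outcome.iloc[loc[present]]
    ea = _allele_codes(exp["effect_allele"].to_numpy())
    oa = _allele_codes(exp["other_allele"].to_numpy())
    eb = _allele_codes(out["effect_allele"].to_numpy())
    ob = _allele_codes(out["other_allele"].to_numpy())
    valid = (ea >= 0) & (oa >= 0) & (eb >= 0) & (ob >= 0)
    palindromic = valid & ((ea + oa == 3) | (eb + ob == 3))
    direct = (eb == ea) & (ob == oa) | (eb == 3 - ea) & (ob == 3 - oa)
    swapped = (eb == oa) & (ob == ea) | (eb == 3 - oa) & (ob == 3 - ea)
    usable = valid & ~palindromic & (direct | swapped)
    sub = reasons[present]
    sub[palindromic] = PALINDROMIC
    sub[~usable & ~palindromic] = AMBIGUOUS
    sub[usable] = None
    reasons[present] = sub

    kept = exp.loc[usable]
    out_kept = out.loc[usable]
    flipped = swapped[usable]
    beta_o = out_kept["beta"].to_numpy()
    instruments = pd.DataFrame(
        {
            "rsid": kept["rsid"].to_numpy(),
            "chrom": kept["chrom"].to_numpy(),
            "pos": kept["pos"].to_numpy(),
            "beta_exp": kept["beta"].to_numpy(),
            "se_exp": kept["se"].to_numpy(),
            "p_exp": kept["pvalue"].to_numpy(),
            "n_exp": kept["n"].to_numpy(),
            "beta_out": np.where(flipped, -beta_o, beta_o),
            "se_out": out_kept["se"].to_numpy(),
            "p_out": out_kept["pvalue"].to_numpy(),
            "n_out": out_kept["n"].to_numpy(dtype=np.int64),
            "eaf_exp": kept["eaf"].to_numpy(),
            "flipped": flipped,
        }
    )
    excluded = reasons != None  # noqa: E711  (elementwise on object array)
    exclusion_frame = pd.DataFrame(
        {"rsid": exp_rsid[excluded], "reason": reasons[excluded]}
    )
    return instruments, exclusion_frame


def write_exclusions(exclusions: pd.DataFrame, path: str | Path) -> None:
    """Write the harmonization exclusion report (`rsid reason`) as TSV."""
    exclusions.to_csv(path, sep="\t", index=False)
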