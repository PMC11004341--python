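"""Bidirectional many-trait screening and Venn intersection.

Each candidate trait is analysed against the anchor phenotype in both
directions. The forward IVW p-value (random-effects when Cochran's Q signals
heterogeneity) drives significance at a nominal alpha = 0.05; traits with a
significant forward effect but a pleiotropy signal (Egger-intercept p or
MR-PRESSO global p below ``pleiotropy_alpha``) are excluded, and traits that
are also significant in reverse are classified bidirectional and likewise
dropped from mediator nomination. Intersecting the exposure->trait and
trait->outcome screens nominates candidate mediators, mirroring the
Venn-diagram step of the study design. No multiple-testing correction is
applied by default (nominal p < 0.05 screening); an optional
Benjamini-Hochberg flag adjusts the forward p-values across traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._utils import derive_seed
from .analysis import DirectionResult, EstimatorSettings, analyze_direction
from .exceptions import ConfigError
from .instruments import LDTable, SelectionConfig
from .sumstats import SumStats

CLASSIFICATIONS = (
    "unidirectional_forward",
    "unidirectional_reverse",
    "bidirectional",
    "null",
    "excluded_pleiotropy",
)

#: leaner battery than the single-pair default: classification consumes only
#: IVW p, Egger intercept p and PRESSO global p, so the mode estimator and
#: large bootstrap/simulation counts are unnecessary at screen scale
def _screen_settings() -> EstimatorSettings:
    return EstimatorSettings(
        n_boot=200,
        presso_n_sim=200,
        methods=("ivw_fixed", "ivw_random", "egger", "weighted_median"),
    )


@dataclass
class ScreenConfig:
    """Thresholds and per-pair settings for one screen."""

    alpha: float = 0.05
    pleiotropy_alpha: float = 0.05
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    settings: EstimatorSettings = field(default_factory=_screen_settings)
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.pleiotropy_alpha < 1:
            raise ConfigError("pleiotropy_alpha must be in (0, 1)")


@dataclass
class TraitScreenRecord:
    """Bidirectional result and classification for one candidate trait."""

    trait_id: str
    forward: DirectionResult
    reverse: DirectionResult
    classification: str
    forward_p: float | None = None
    reverse_p: float | None = None
    warnings: list[str] = field(default_factory=list)


def _pleiotropy_flag(direction: DirectionResult, alpha: float) -> bool:
    sens = direction.sensitivity
    if sens is None:
        return False
    if sens.egger_intercept_p is not None and sens.egger_intercept_p < alpha:
        return True
    if sens.presso is not None and sens.presso.global_p < alpha:
        return True
    return False


def classify(
    forward: DirectionResult,
    reverse: DirectionResult,
    config: ScreenConfig,
    forward_p: float | None = None,
    reverse_p: float | None = None,
) -> str:
    """Classify a bidirectional pair; p overrides support BH-adjusted values."""
    if forward_p is None and forward.estimable:
        forward_p = forward.primary.pvalue
    if reverse_p is None and reverse.estimable:
        reverse_p = reverse.primary.pvalue
    fsig = forward_p is not None and forward_p < config.alpha
    rsig = reverse_p is not None and reverse_p < config.alpha
    if fsig and _pleiotropy_flag(forward, config.pleiotropy_alpha):
        return "excluded_pleiotropy"
    if fsig and rsig:
        return "bidirectional"
    if fsig:
        return "unidirectional_forward"
    if rsig:
        return "unidirectional_reverse"
    return "null"


def screen_pair(
    exposure: SumStats,
    trait: SumStats,
    ld: LDTable | None = None,
    config: ScreenConfig | None = None,
    seed: int = 0,
    trait_id: str | None = None,
) -> TraitScreenRecord:
    """Run the full per-pair pipeline in both directions and classify.

    Forward is exposure -> trait; reverse is trait -> exposure. A direction
    with no surviving instruments is marked inestimable and classification
    falls back to the available direction with a warning.
    """
    config = config or ScreenConfig()
    trait_id = trait_id or trait.trait
    forward = analyze_direction(
        exposure, trait, ld=ld, selection=config.selection,
        settings=config.settings, seed=derive_seed(seed, f"fwd:{trait_id}"),
    )
    reverse = analyze_direction(
        trait, exposure, ld=ld, selection=config.selection,
        settings=config.settings, seed=derive_seed(seed, f"rev:{trait_id}"),
    )
    warnings = []
    if not forward.estimable:
        warnings.append("forward_inestimable")
    if not reverse.estimable:
        warnings.append("reverse_inestimable")
    record = TraitScreenRecord(
        trait_id=trait_id,
        forward=forward,
        reverse=reverse,
        classification=classify(forward, reverse, config),
        forward_p=forward.primary.pvalue if forward.estimable else None,
        reverse_p=reverse.primary.pvalue if reverse.estimable else None,
        warnings=warnings,
    )
    return record


def screen_traits(
    exposure: SumStats,
    traits: Mapping[str, SumStats],
    ld: LDTable | None = None,
    config: ScreenConfig | None = None,
    seed: int = 0,
) -> dict[str, TraitScreenRecord]:
    """Screen every trait against the exposure; optionally BH-adjust forward p."""
    config = config or ScreenConfig()
    records = {
        trait_id: screen_pair(
            exposure, stats, ld=ld, config=config, seed=seed, trait_id=trait_id
        )
        for trait_id, stats in traits.items()
    }
    if config.bh_correct and records:
        ids = [t for t, r in records.items() if r.forward_p is not None]
        if ids:
            raw = [records[t].forward_p for t in ids]
            adjusted = multipletests(raw, method="fdr_bh")[1]
            for trait_id, adj in zip(ids, adjusted):
                rec = records[trait_id]
                rec.forward_p = float(adj)
                rec.classification = classify(
                    rec.forward, rec.reverse, config,
                    forward_p=rec.forward_p, reverse_p=rec.reverse_p,
                )
    return records


def intersect_screens(
    screen_a: Mapping[str, TraitScreenRecord],
    screen_b: Mapping[str, TraitScreenRecord],
) -> list[str]:
    """Traits unidirectionally forward-significant in both screens, sorted."""
    hits = [
        trait_id
        for trait_id, rec in screen_a.items()
        if rec.classification == "unidirectional_forward"
        and trait_id in screen_b
        and screen_b[trait_id].classification == "unidirectional_forward"
    ]
    return sorted(hits)


def screen_report_frame(records: Mapping[str, TraitScreenRecord]) -> pd.DataFrame:
    rows = []
    for trait_id, rec in records.items():
        def _side(d: DirectionResult, p):
            sens = d.sensitivity
            return {
                "n_snps": d.n_instruments,
                "beta": d.primary.beta if d.estimable else None,
                "se": d.primary.se if d.estimable else None,
                "p": p,
                "q_p": sens.heterogeneity.pvalue if sens and sens.heterogeneity else None,
                "egger_intercept_p": sens.egger_intercept_p if sens else None,
                "presso_global_p": sens.presso.global_p if sens and sens.presso else None,
            }

        fwd = {f"forward_{k}": v for k, v in _side(rec.forward, rec.forward_p).items()}
        rev = {f"reverse_{k}": v for k, v in _side(rec.reverse, rec.reverse_p).items()}
        rows.append(
            {"trait_id": trait_id, **fwd, **rev, "classification": rec.classification}
        )
    return pd.DataFrame(rows)


def write_screen_report(records: Mapping[str, TraitScreenRecord], path) -> None:
    screen_report_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_venn(trait_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        for trait_id in trait_ids:
            fh.write(f"{trait_id}\n")
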