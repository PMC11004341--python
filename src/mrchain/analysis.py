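"""Per-pair analysis driver: selection -> Steiger filter -> estimators -> sensitivity.

This is the unit of work shared by the bidirectional total-effect stage and
the many-trait screens; each invocation analyses one directed exposure ->
outcome pair end to end on summary statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._utils import derive_seed
from .estimators import METHODS, MREstimate, estimate_all
from .instruments import LDTable, SelectionConfig, select_instruments
from .sensitivity import SensitivityReport, sensitivity_battery, steiger_filter
from .sumstats import SumStats


@dataclass
class EstimatorSettings:
    """Tunable knobs shared by the estimator/sensitivity stack.

    n_boot: parametric-bootstrap draws for weighted median/mode SEs.
    presso_n_sim: MR-PRESSO simulation count.
    bandwidth_factor: weighted-mode kernel bandwidth multiplier.
    steiger_alpha: significance needed to discard a wrong-direction SNP.
    steiger_strict: discard on wrong direction alone, ignoring steiger_p.
    or_scale: also report exponentiated (odds-ratio) effects.
    """

    n_boot: int = 1000
    presso_n_sim: int = 1000
    bandwidth_factor: float = 1.0
    methods: tuple[str, ...] = METHODS
    steiger_alpha: float = 0.05
    steiger_strict: bool = False
    or_scale: bool = True


@dataclass
class DirectionResult:
    """Everything computed for one directed exposure -> outcome analysis."""

    exposure: str
    outcome: str
    instruments: pd.DataFrame
    selection_report: pd.DataFrame
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    primary: MREstimate | None = None
    sensitivity: SensitivityReport | None = None
    steiger: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def estimable(self) -> bool:
        return self.primary is not None

    @property
    def n_instruments(self) -> int:
        return len(self.instruments)


def analyze_direction(
    exposure: SumStats,
    outcome: SumStats,
    ld: LDTable | None = None,
    selection: SelectionConfig | None = None,
    settings: EstimatorSettings | None = None,
    seed: int = 0,
) -> DirectionResult:
    """Analyse one directed pair; inestimable directions return warnings, not errors."""
    selection = selection or SelectionConfig()
    settings = settings or EstimatorSettings()
    result = DirectionResult(
        exposure=exposure.trait,
        outcome=outcome.trait,
        instruments=pd.DataFrame(),
        selection_report=pd.DataFrame(columns=["rsid", "disposition"]),
    )

    instr, report = select_instruments(exposure, outcome, ld=ld, config=selection)
    result.selection_report = report
    if len(instr) == 0:
        result.warnings.append("no_instruments_after_selection")
        return result

    instr, steiger = steiger_filter(
        instr, alpha=settings.steiger_alpha, strict=settings.steiger_strict
    )
    result.steiger = steiger
    n_discarded = int(steiger["discarded"].sum())
    if len(instr) == 0:
        result.warnings.append("no_instruments_after_steiger")
        return result
    result.instruments = instr

    result.estimates = estimate_all(
        instr,
        methods=settings.methods,
        n_boot=settings.n_boot,
        seed=derive_seed(seed, f"boot:{exposure.trait}:{outcome.trait}"),
        bandwidth_factor=settings.bandwidth_factor,
        or_scale=settings.or_scale,
    )
    if len(instr) < 3:
        result.warnings.append("ivw_only_few_instruments")

    result.sensitivity = sensitivity_battery(
        instr,
        egger_estimate=result.estimates.get("egger"),
        presso_n_sim=settings.presso_n_sim,
        seed=derive_seed(seed, f"presso:{exposure.trait}:{outcome.trait}"),
    )
    result.sensitivity.steiger = steiger
    result.sensitivity.steiger_n_discarded = n_discarded

    # primary estimate per the heterogeneity rule: random-effects IVW only
    # when Cochran's Q signals heterogeneity at p < 0.05
    het = result.sensitivity.heterogeneity
    if het is not None and het.pvalue < 0.05 and "ivw_random" in result.estimates:
        result.primary = result.estimates["ivw_random"]
    else:
        result.primary = result.estimates.get("ivw_fixed")
    return result
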