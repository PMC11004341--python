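"""Two-step MR mediation: decompose the total effect through a mediator trait.

With c the total exposure->outcome effect (log-odds per unit exposure), a the
exposure->mediator effect (mediator SD units) and b the mediator->outcome
effect (log-odds per mediator SD), the indirect path is a*b, the direct
remainder c' = c - a*b, and the mediated proportion is (a*b)/c, reported as a
percentage. The indirect-effect SE uses the product-normal (Sobel) delta
method without a covariance term — the two legs come from non-overlapping
regressions — and the proportion interval divides the indirect interval by c
with c treated as fixed.

b comes from univariable MR of mediator->outcome (two-step design), not from
a multivariable model adjusting for the exposure; the resulting bias when
the exposure also acts directly on the outcome through the mediator's
instruments is a documented limitation, not corrected here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .estimators import MREstimate, Z95
from .screening import TraitScreenRecord


@dataclass
class MediationResult:
    """a/b/c decomposition with delta-method uncertainty.

    ``proportion_pct`` is the mediated proportion as a percentage, reported
    to three decimals in the TSV output.
    """

    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float
    se_indirect: float
    indirect_ci_low: float
    indirect_ci_high: float
    c_prime: float
    proportion_pct: float
    prop_ci_low: float
    prop_ci_high: float
    qualified: bool = True


@dataclass
class MediatorQualification:
    """Eligibility of one trait as mediator on the exposure -> outcome path."""

    trait_id: str
    forward_exposure_p: float | None
    reverse_exposure_p: float | None
    forward_outcome_p: float | None
    reverse_outcome_p: float | None
    sign_consistent: bool
    qualified: bool


def decompose(
    c: MREstimate,
    a: MREstimate,
    b: MREstimate,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
    qualified: bool = True,
) -> MediationResult:
    """Decompose the total effect c into indirect a*b and direct c - a*b."""
    if c.beta == 0:
        raise ValueError("undefined mediated proportion: total effect c is zero")
    indirect = a.beta * b.beta
    se_indirect = math.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2)
    ci_low = indirect - Z95 * se_indirect
    ci_high = indirect + Z95 * se_indirect
    prop = indirect / c.beta
    prop_bounds = sorted((ci_low / c.beta, ci_high / c.beta))
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        a=a.beta,
        se_a=a.se,
        b=b.beta,
        se_b=b.se,
        c=c.beta,
        se_c=c.se,
        indirect=indirect,
        se_indirect=se_indirect,
        indirect_ci_low=ci_low,
        indirect_ci_high=ci_high,
        c_prime=c.beta - indirect,
        proportion_pct=100.0 * prop,
        prop_ci_low=100.0 * prop_bounds[0],
        prop_ci_high=100.0 * prop_bounds[1],
        qualified=qualified,
    )


def qualify_mediator(
    screen_exposure: TraitScreenRecord,
    screen_outcome: TraitScreenRecord,
    c_beta: float,
    alpha: float = 0.05,
) -> MediatorQualification:
    """Check the mediator eligibility rules for one trait.

    Qualification requires both legs significant in the mediating direction,
    neither reverse direction significant (unidirectionality), and sign
    consistency sign(a*b) == sign(c) — a trait whose two legs imply an effect
    opposing the total effect cannot mediate it.
    """
    fwd_exp = screen_exposure.forward_p
    rev_exp = screen_exposure.reverse_p
    fwd_out = screen_outcome.forward_p
    rev_out = screen_outcome.reverse_p
    a = screen_exposure.forward.primary.beta if screen_exposure.forward.estimable else None
    b = screen_outcome.forward.primary.beta if screen_outcome.forward.estimable else None
    sign_consistent = (
        a is not None
        and b is not None
        and a * b != 0
        and math.copysign(1.0, a * b) == math.copysign(1.0, c_beta)
    )
    unidirectional = (
        fwd_exp is not None
        and fwd_exp < alpha
        and (rev_exp is None or rev_exp >= alpha)
        and fwd_out is not None
        and fwd_out < alpha
        and (rev_out is None or rev_out >= alpha)
    )
    return MediatorQualification(
        trait_id=screen_exposure.trait_id,
        forward_exposure_p=fwd_exp,
        reverse_exposure_p=rev_exp,
        forward_outcome_p=fwd_out,
        reverse_outcome_p=rev_out,
        sign_consistent=bool(sign_consistent),
        qualified=bool(unidirectional and sign_consistent),
    )


MEDIATION_TSV_COLUMNS = [
    "exposure",
    "mediator",
    "outcome",
    "a",
    "se_a",
    "b",
    "se_b",
    "c",
    "se_c",
    "indirect",
    "se_indirect",
    "c_prime",
    "proportion_pct",
    "prop_ci_low",
    "prop_ci_high",
    "qualified",
]


def mediation_frame(results: list[MediationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {k: getattr(r, k) for k in MEDIATION_TSV_COLUMNS}
        for key in ("proportion_pct", "prop_ci_low", "prop_ci_high"):
            row[key] = round(row[key], 3)
        rows.append(row)
    return pd.DataFrame(rows, columns=MEDIATION_TSV_COLUMNS)


def write_mediation(results: list[MediationResult], path) -> None:
    mediation_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")
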