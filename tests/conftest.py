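import numpy as np
import pandas as pd
import pytest

from mrchain.sumstats import CANONICAL_COLUMNS, SumStats


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical summary-statistics frame from sparse row dicts."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pvalue": 1e-8,
        "n": 100_000,
    }
    full = []
    for i, row in enumerate(rows):
        rec = {"rsid": f"rs{i}", **defaults, **row}
        full.append(rec)
    return pd.DataFrame(full)[CANONICAL_COLUMNS]


def make_sumstats(rows: list[dict], trait: str = "trait") -> SumStats:
    return SumStats(make_frame(rows), trait=trait)


@pytest.fixture
def three_instruments() -> pd.DataFrame:
    """The worked three-instrument set with exact IVW solution 0.108/0.21."""
    return pd.DataFrame(
        {
            "rsid": ["s1", "s2", "s3"],
            "beta_exp": [0.1, 0.2, 0.4],
            "se_exp": [0.01, 0.01, 0.01],
            "p_exp": [1e-10, 1e-10, 1e-10],
            "n_exp": [100_000] * 3,
            "beta_out": [0.06, 0.09, 0.21],
            "se_out": [0.02, 0.02, 0.02],
            "p_out": [0.01, 0.01, 0.01],
            "n_out": [100_000] * 3,
        }
    )


@pytest.fixture
def proportional_instruments() -> pd.DataFrame:
    """Instruments with beta_out exactly 0.5 * beta_exp (zero heterogeneity)."""
    bx = np.array([0.05, 0.08, 0.1, 0.12, 0.15])
    return pd.DataFrame(
        {
            "rsid": [f"p{i}" for i in range(5)],
            "beta_exp": bx,
            "se_exp": 0.005,
            "p_exp": 1e-12,
            "n_exp": 100_000,
            "beta_out": 0.5 * bx,
            "se_out": 0.01,
            "p_out": 0.001,
            "n_out": 100_000,
        }
    )
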