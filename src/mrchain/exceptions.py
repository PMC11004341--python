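"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
AnalysisError -> 4.
"""


class MRChainError(Exception):
    """Base class for all package errors."""


class ConfigError(MRChainError):
    """Invalid or inconsistent configuration (bad thresholds, missing columns)."""


class DataError(MRChainError):
    """Unreadable or structurally invalid input data."""


class AnalysisError(MRChainError):
    """An analysis stage could not produce a result (e.g. no instruments left)."""


class InsufficientInstrumentsError(AnalysisError):
    """Fewer instruments than the estimator's minimum (3 for Egger/median/mode)."""
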