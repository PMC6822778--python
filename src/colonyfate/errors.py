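"""Exception hierarchy shared across the package."""


class ColonyFateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColonyFateError, ValueError):
    """Invalid parameter, grid, or threshold configuration."""


class IntegrationError(ColonyFateError, RuntimeError):
    """Numerical failure (blow-up or negativity) during time integration."""


class AnalysisError(ColonyFateError, RuntimeError):
    """Linear-stability or statistic computation cannot proceed."""


class GenerationError(ColonyFateError, RuntimeError):
    """Synthetic-data generation failed (e.g. packing or count matching)."""


class InputError(ColonyFateError, ValueError):
    """Malformed or incomplete input table."""
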