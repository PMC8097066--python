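"""Exception types shared across the package."""


class CellHydroError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CellHydroError, ValueError):
    """An argument is outside the physically meaningful domain."""


class NormalizationError(CellHydroError, ValueError):
    """A probability column cannot be normalized (off-diagonal sum > 1)."""


class DegenerateDistributionError(CellHydroError, ValueError):
    """A scission distribution has collapsed to zero spread (sigma = 0)."""


class ConfigError(CellHydroError, ValueError):
    """A run configuration file is invalid."""
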