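"""Exception hierarchy.

All thermirl errors derive from :class:`ThermirlError` so callers can catch
the package's failures with one clause; the subclasses distinguish bad
configuration, bad input data, malformed files, violated model contracts,
and numerical failures (non-convergence).
"""


class ThermirlError(Exception):
    """Base class for all thermirl errors."""


class ConfigurationError(ThermirlError, ValueError):
    """A spec/config object violates one of its invariants."""


class DataError(ThermirlError, ValueError):
    """Input data are unusable (empty, non-monotone time, non-finite, ...)."""


class FormatError(ThermirlError, ValueError):
    """A file does not match the expected layout (missing columns, ...)."""


class ModelError(ThermirlError, ValueError):
    """A model contract is violated (zero kernel row, absolute continuity, ...)."""


class NumericalError(ThermirlError, RuntimeError):
    """An iterative numerical procedure failed to converge."""
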