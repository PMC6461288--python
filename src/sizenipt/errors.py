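"""Exception hierarchy.

All package errors derive from SizeNiptError so callers (and the CLI) can
distinguish validation problems from programming errors.
"""


class SizeNiptError(Exception):
    """Base class for all package errors."""


class FormatError(SizeNiptError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(SizeNiptError):
    """Input data violates an invariant (negative count, bad label, ...)."""


class DegenerateSampleError(SizeNiptError):
    """A sample has no usable fragments under the requested restriction."""


class DegenerateTrainingError(SizeNiptError):
    """Training statistics cannot support a z-score (zero SD)."""


class ConfigurationError(SizeNiptError):
    """A protocol or simulation configuration is inconsistent."""


class EvaluationError(SizeNiptError):
    """Calls cannot be scored (e.g. unknown truth labels)."""


class SearchError(SizeNiptError):
    """The boundary search cannot proceed (empty grids, no valid candidate)."""
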