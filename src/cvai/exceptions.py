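"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration/parameter problems -> 2,
data/format problems -> 3, anything else raised by a stage -> 4.
"""


class CvaiError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CvaiError, ValueError):
    """An operation was called with an invalid parameter (e.g. even block size)."""


class ConfigError(ParameterError):
    """A configuration file or CLI option could not be resolved."""


class FormatError(CvaiError, ValueError):
    """An input file decoded but does not have the expected structure."""


class DataError(CvaiError, ValueError):
    """Tabular input violates the cohort schema or its invariants."""


class EmptyFieldError(CvaiError, ValueError):
    """No illuminated field of view could be found (IR would be zero)."""


class DegenerateMaskError(CvaiError, ValueError):
    """A mask is unusable for its purpose (e.g. retinal mask covers the image)."""


class DegenerateStatisticError(CvaiError, ValueError):
    """A statistic is undefined on this input (zero variance, one class...)."""
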