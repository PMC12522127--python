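"""Exception hierarchy.

All package errors derive from :class:`FibrionError` so callers can catch one
type; configuration problems and data problems are distinguished because the
command-line layer maps them to different exit codes (2 and 3).
"""


class FibrionError(Exception):
    """Base class for all errors raised by fibrion."""


class ConfigError(FibrionError):
    """Invalid configuration, schema violation, or unknown parameter."""


class DataError(FibrionError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A structure or trajectory file could not be parsed."""


class TopologyMismatchError(DataError):
    """Trajectory atom count does not match the structure's topology."""


class UnsupportedBoxError(DataError):
    """Simulation cell is not orthorhombic."""


class EmptySelectionError(DataError):
    """An atom selection matched nothing."""


class GeometryError(DataError):
    """Synthetic-system geometry is infeasible (e.g. binding sites too dense)."""


class ParameterError(ConfigError):
    """A numeric parameter is out of its valid range."""


class DegenerateDistributionError(DataError):
    """A distance distribution has no usable peak structure."""


class EmptyDistributionError(DataError):
    """No distances fell inside the histogram range."""


class NoShellError(DataError):
    """g(r) has no first-shell structure (no prominent maximum/minimum)."""


class BoxSizeError(DataError):
    """Requested cutoff or r_max exceeds half the smallest box edge."""


class UnknownIonError(ConfigError):
    """Ion symbol not present in the shipped Hofmeister table."""
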