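"""Exception hierarchy shared across the pipeline."""


class LineagevarError(Exception):
    """Base class for all package errors."""


class InputError(LineagevarError):
    """Malformed, empty or otherwise unusable input."""


class SchemaError(InputError):
    """A tabular input is missing required columns."""


class AlignmentError(InputError):
    """Sequences that should form an alignment have unequal lengths."""


class AlphabetError(InputError):
    """A residue string contains symbols outside the allowed alphabet."""


class PreconditionError(LineagevarError):
    """An operation was called on data violating its stated precondition."""


class UndefinedDistanceError(LineagevarError):
    """A pairwise distance has no comparable sites and is undefined."""


class ConfigError(LineagevarError):
    """A simulation or pipeline configuration is invalid."""


class NewickParseError(InputError):
    """A Newick string could not be parsed; message carries the position."""
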