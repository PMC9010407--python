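"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (missing input -> 2, parameter -> 3,
empty result -> 4); library users catch them like ordinary ValueErrors.
"""


class ScassignError(ValueError):
    """Base class for all package errors."""


class FormatError(ScassignError):
    """Malformed or inconsistent input file."""


class ParameterError(ScassignError):
    """Invalid parameter value or combination."""


class EmptyResultError(ScassignError):
    """An operation removed every cell/gene/cluster."""
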