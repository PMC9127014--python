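"""Exception hierarchy.

Validation/configuration problems (bad inputs, bad parameter files) map to CLI
exit code 2; violated internal invariants (e.g. decomposition components that
fail to sum to the total difference) map to exit code 3.
"""


class DpgapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DpgapError):
    """A scenario or parameter set violates its contract."""


class ValidationError(DpgapError):
    """An input table or record collection violates its contract."""


class InvariantError(DpgapError):
    """A computed result violates an internal invariant."""
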