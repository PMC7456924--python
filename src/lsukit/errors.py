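"""Exception hierarchy shared across the package.

Exit codes (used by the CLI): 2 configuration, 3 validation, 4 I/O.
"""


class LsukitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(LsukitError):
    """Inconsistent or unknown configuration (bad keys, unmapped columns)."""

    exit_code = 2


class ValidationError(LsukitError):
    """Input data violates a documented invariant."""

    exit_code = 3


class DegenerateModelError(ValidationError):
    """A register shift leaves too few residues placed to form a dimer."""


class InputError(LsukitError):
    """File missing, unreadable, or unwritable."""

    exit_code = 4
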