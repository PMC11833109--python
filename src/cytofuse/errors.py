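"""Exception hierarchy.

Validation problems (bad configuration, malformed input) are distinguished
from runtime numeric failures so the CLI can map them to distinct exit codes.
"""


class CytofuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytofuseError):
    """A configuration field is invalid; the message names the field."""


class InputError(CytofuseError):
    """Operation input violates a precondition."""


class StructuralError(InputError):
    """A sequence or container violates a structural invariant
    (e.g. a dispense sequence not bounded by marker beads)."""


class NumericError(CytofuseError):
    """Non-finite values where finite numbers are required."""
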