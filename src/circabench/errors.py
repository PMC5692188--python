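"""Exception types shared across the package.

``ValidationError`` maps to CLI exit code 2, ``CapacityError`` to 3.
"""


class CircabenchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CircabenchError, ValueError):
    """Invalid configuration, arguments, or file contents."""


class CapacityError(CircabenchError, RuntimeError):
    """A request exceeds a hard computational capacity limit."""
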