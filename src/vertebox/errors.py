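"""Exception types shared across the package."""


class VerteBoxError(Exception):
    """Base class for package errors."""


class InvalidInputError(VerteBoxError, ValueError):
    """An input array or file violates an operation's preconditions."""


class ConfigurationError(VerteBoxError, ValueError):
    """A configuration value violates a structural invariant."""


class EmptyMaskError(VerteBoxError, ValueError):
    """A boundary-distance metric was requested for an empty mask."""


class DegenerateInputError(VerteBoxError, ValueError):
    """A statistical test received data with no variance."""
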