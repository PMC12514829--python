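"""Exceptions shared across the package."""


class OxyscopeError(Exception):
    """Base class for package errors."""


class ValidationError(OxyscopeError, ValueError):
    """An input violated a physical or structural invariant."""


class NoConformityError(OxyscopeError):
    """Raised when breakpoint regression finds no oxygen-conforming limb."""
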