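"""Exception types shared across the package."""


class CpgscapeError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(CpgscapeError):
    """An input object violates a structural invariant."""


class IncompatibilityError(CpgscapeError):
    """Two objects that must share a genome or bin grid do not."""


class DegenerateInputError(CpgscapeError):
    """Input is structurally valid but the operation is undefined on it
    (all-zero track, zero-variance vector, empty region set, ...)."""
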