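"""Exception hierarchy shared by all crmap modules."""


class CrmapError(Exception):
    """Base class for all crmap-specific errors."""


class InvalidInputError(CrmapError, ValueError):
    """Raised when user-supplied data is malformed (non-finite, empty, wrong size)."""


class ContractViolationError(CrmapError, ValueError):
    """Raised when paired objects disagree on dimensions or metadata."""


class UnsupportedArchitectureError(CrmapError, TypeError):
    """Raised when a model does not expose the conv -> GAP -> dense head shape."""


class ConfigurationError(CrmapError, ValueError):
    """Raised when a configuration would produce an unusable object."""


class EmptyROIError(CrmapError, ValueError):
    """Raised when a relative threshold selects no pixels (e.g. all-zero map)."""
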