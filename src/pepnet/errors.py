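"""Exception hierarchy shared across the package."""


class PepnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PepnetError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(PepnetError):
    """Input data violate a documented invariant."""


class DesignError(PepnetError):
    """The study design is inconsistent with the data or the requested operation."""
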