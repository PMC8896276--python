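"""Exception hierarchy shared across the package."""


class Pm5Error(Exception):
    """Base class for all package errors."""


class FormatError(Pm5Error):
    """A tabular input does not have the expected shape (e.g. missing column)."""


class ValidationError(Pm5Error, ValueError):
    """A value violates a domain invariant (bad residue, inconsistent coordinates...)."""


class ConfigurationError(Pm5Error):
    """A run configuration references unknown tools, sources or files."""
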