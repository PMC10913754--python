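"""Exception hierarchy shared across the package."""


class EcoAssemblyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EcoAssemblyError):
    """A file could not be parsed, or violated its format contract."""


class ValidationError(EcoAssemblyError):
    """An in-memory object violated a stated invariant or argument bound."""


class ConsistencyError(EcoAssemblyError):
    """Two otherwise-valid objects disagree (sample/taxon sets, pair sets)."""
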