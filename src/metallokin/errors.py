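"""Exception hierarchy."""


class MetallokinError(Exception):
    """Base class for all package errors."""


class SchemaError(MetallokinError):
    """A required column or field is missing from an input table."""


class TableParseError(MetallokinError):
    """An input cell could not be parsed (e.g. non-numeric energy)."""


class DuplicateLabelError(MetallokinError):
    """Two species share the same label."""


class SpeciesLookupError(MetallokinError):
    """A reaction references a label with no species record."""


class BalanceError(MetallokinError):
    """A reaction fails charge or atom bookkeeping."""


class ConfigError(MetallokinError):
    """An invalid configuration value (unknown convention, bad range...)."""


class IdentifiabilityError(MetallokinError):
    """A regression design does not identify the requested parameter."""


class ConvergenceError(MetallokinError):
    """An iterative solve failed to converge; carries diagnostics."""
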