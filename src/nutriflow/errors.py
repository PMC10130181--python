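"""Exception hierarchy for the nutriflow pipeline."""


class NutriflowError(Exception):
    """Base class for all package errors."""


class SchemaError(NutriflowError):
    """An input table is missing required columns."""


class ValidationError(NutriflowError):
    """An input value violates a domain invariant (e.g. negative mass)."""


class UnitError(NutriflowError):
    """An unrecognised or unsupported unit string."""


class ContentLookupError(NutriflowError, KeyError):
    """A nutrient content could not be resolved for a (country, product)."""


class InconsistencyError(NutriflowError):
    """Mutually inconsistent inputs (e.g. exports with zero supply)."""


class ConfigurationError(NutriflowError):
    """Invalid or incomplete run/world configuration."""
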