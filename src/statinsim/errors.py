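"""Exception hierarchy for the statinsim pipeline."""


class StatinsimError(Exception):
    """Base class for all package-specific errors."""


class InputError(StatinsimError):
    """A required input file is missing or unreadable."""


class ValidationError(StatinsimError):
    """A table row violates the documented schema (bad date, non-positive dose, ...)."""


class CatalogError(StatinsimError):
    """Unknown statin molecule or dose outside every configured band."""


class ParameterError(StatinsimError):
    """Infeasible numeric parameters (e.g. beta moments outside the feasible region)."""


class ConfigurationError(StatinsimError):
    """Malformed configuration: unknown signal name, missing effect model, ..."""


class ConsistencyError(StatinsimError):
    """Cross-table inconsistency (e.g. a classified patient without a risk profile)."""


class SpecificationError(StatinsimError):
    """An infeasible synthetic-cohort specification."""
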