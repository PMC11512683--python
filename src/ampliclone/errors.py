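"""Exception hierarchy shared across the package."""


class AmplicloneError(Exception):
    """Base class for all package errors."""


class FormatError(AmplicloneError):
    """A table is missing a required column or is otherwise malformed."""


class ValidationError(AmplicloneError):
    """A table violates a data-model invariant (duplicates, negative counts, orphans)."""


class ConfigurationError(AmplicloneError):
    """The run configuration or its referenced entities are invalid (e.g. no WT-control cells)."""


class EstimationError(AmplicloneError):
    """Too little data to estimate a quantity (control thresholds, ADO rates, phase)."""


class InsufficientDataError(EstimationError):
    """Alias-style error for operations that need a minimum number of cells."""


class StructureError(AmplicloneError):
    """The scVAF distribution lacks the multi-peak structure required for minima-based calling."""


class ContractError(AmplicloneError):
    """Caller violated an internal contract (mismatched cell/mutation identifiers)."""


class SizeError(AmplicloneError):
    """Problem exceeds the supported exhaustive-search regime (too many mutations)."""
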