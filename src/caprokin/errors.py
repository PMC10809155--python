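"""Exception hierarchy shared across the package."""


class CaprokinError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CaprokinError):
    """An input table is missing a required column or has a bad header."""


class ValidationError(CaprokinError):
    """Input values violate a data invariant (non-monotone times, signal <= 0 ...)."""


class ContractError(CaprokinError):
    """An operation was called with arguments outside its contract."""


class EstimationError(CaprokinError):
    """A fit failed: no start converged, or too many bootstrap refits failed."""


class PropagationError(CaprokinError):
    """Monte-Carlo propagation produced no finite draws."""


class RegistryError(CaprokinError):
    """A compound is not present in the compound registry."""
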