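"""Exception hierarchy for the overyield package."""


class OveryieldError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OveryieldError):
    """A table is missing a required column or has the wrong layout."""


class ReferentialError(OveryieldError):
    """A row refers to a plot or species that does not exist in the design."""


class ValidationError(OveryieldError):
    """A value violates a dataset invariant (range, sum, consistency)."""


class ConfigurationError(OveryieldError):
    """The requested computation is impossible with the given inputs,
    e.g. an active species without a monoculture reference."""


class DesignError(OveryieldError):
    """The experimental design cannot support the requested model
    (rank deficiency, saturated model, infeasible balance)."""


class FitError(OveryieldError):
    """A model fit failed to converge or produced non-finite results."""
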