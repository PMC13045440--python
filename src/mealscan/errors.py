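"""Exception hierarchy shared across the package."""


class MealscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MealscanError, ValueError):
    """A configuration object violates its invariants (bad state name,
    negative distribution parameter, non-positive energy density ...)."""


class ValidationError(MealscanError, ValueError):
    """Input data violate a documented contract (overlapping events,
    unknown animal id, events inside a starvation window ...)."""


class ContractError(MealscanError, ValueError):
    """An operation was called outside its precondition (unsorted input,
    missing phase, window not covered by the record ...)."""


class ParseError(MealscanError, ValueError):
    """A file could not be parsed under the documented CSV/YAML dialect."""


class DegenerateDataError(MealscanError, ValueError):
    """Data are degenerate for the requested statistic (e.g. zero variance
    of paired differences with a non-zero mean difference)."""
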