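"""Exception hierarchy shared across the pipeline."""


class LdhError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LdhError, ValueError):
    """A configuration object violates its invariants."""


class InputError(LdhError, ValueError):
    """Input data violate a precondition (too few points, mismatched shapes...)."""


class DomainError(LdhError, ValueError):
    """A scalar argument lies outside its valid domain (e.g. VAS not in [0, 10])."""


class ParseError(LdhError, ValueError):
    """A data file could not be validated; the message names the offending row."""


class DegenerateTableError(LdhError, ValueError):
    """A contingency table has a zero marginal, so the chi-square test is undefined."""
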