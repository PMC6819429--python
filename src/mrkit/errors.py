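"""Exception hierarchy.

Everything raised on purpose by mrkit derives from :class:`MrError`, so callers
can catch one type at pipeline level while tests can assert on the specific
subclass.
"""


class MrError(Exception):
    """Base class for all mrkit errors."""


class ParseError(MrError):
    """A summary-statistics table could not be parsed (e.g. missing column)."""


class ValidationError(MrError):
    """An input value violates a domain invariant (SE <= 0, empty set, ...)."""


class HarmonizationError(MrError):
    """Exposure and outcome records cannot be placed on a common allele frame."""


class UndefinedRatioError(MrError):
    """Wald ratio requested for a SNP with a zero exposure effect."""


class InsufficientInstrumentsError(MrError):
    """An estimator was called with fewer SNPs than it requires."""


class ConfigurationError(MrError):
    """A plan or exclusion set references something that does not exist."""


class NoSolutionError(MrError):
    """A power root-solve has no solution inside the search bracket."""
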