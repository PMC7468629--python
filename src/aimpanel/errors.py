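"""Exception hierarchy for the aimpanel package.

Each distinct failure mode named in the data contracts gets its own class so
callers can catch precisely.
"""


class AimPanelError(Exception):
    """Base class for all package errors."""


class DuplicateSampleIdError(AimPanelError):
    """A sample identifier occurs more than once in an input table."""


class UnknownTokenError(AimPanelError):
    """A genotype cell contains a token outside the documented encodings."""


class RaggedRowError(AimPanelError):
    """A TSV row has a different number of fields than the header."""


class UnmappedSampleError(AimPanelError):
    """A VCF sample has no entry in the sample-to-population map."""


class DegenerateLocusError(AimPanelError):
    """A locus has no observed (non-missing) genotypes."""


class EmptyClassError(AimPanelError):
    """A training class contains no individuals."""


class SingletonClassError(AimPanelError):
    """A class has a single individual and cannot be left out."""


class NoUsableLociError(AimPanelError):
    """An individual has no genotype at any trained locus."""


class ConfigError(AimPanelError):
    """A run or simulation configuration violates its invariants."""


class DegenerateSeriesError(AimPanelError):
    """A log-likelihood series has zero spread where a spread is required."""
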