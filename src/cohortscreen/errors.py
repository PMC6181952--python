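"""Exception hierarchy for cohortscreen.

All package errors derive from :class:`CohortScreenError` so callers can
catch the package's failures with a single except clause while still
distinguishing structural problems (format, vocabulary) from statistical
degeneracies (constant vectors, zero variance).
"""


class CohortScreenError(Exception):
    """Base class for all cohortscreen errors."""


class FormatError(CohortScreenError):
    """A table violates its structural contract (missing/duplicated ids,
    wrong dialect, missing required columns)."""


class VocabularyError(FormatError):
    """A categorical column contains a token outside its closed vocabulary."""


class TableParseError(FormatError):
    """A cell could not be parsed as a number; names the offending
    row and column."""


class ScaleError(CohortScreenError):
    """An operation was called on data in the wrong scale
    (raw intensity vs log2)."""


class DomainError(CohortScreenError):
    """A numeric value lies outside the operation's domain
    (nonpositive before log2, p-value outside [0, 1], negative time)."""


class MissingDataError(CohortScreenError):
    """Required optional data (e.g. detection p-values) is absent."""


class MissingGeneError(CohortScreenError):
    """No probe maps to the requested gene in this dataset."""


class SampleSizeError(CohortScreenError):
    """Too few samples/values for the statistic to be defined."""


class DesignError(CohortScreenError):
    """An experimental design is unusable (e.g. a group with < 2 samples)."""


class DegenerateDataError(CohortScreenError):
    """The data are degenerate for the requested statistic
    (constant vector, all variances zero, constant stratification signal)."""


class ConfigurationError(CohortScreenError):
    """A run configuration is inconsistent or references unavailable
    inputs (anchor absent everywhere, missing reference condition,
    unpaired ChIP records, infeasible simulation parameters)."""
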