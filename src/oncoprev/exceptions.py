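"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError/FormatError are
validation errors (exit 2), IntegrityError is a data-integrity error (exit 3),
NumericError covers undefined numeric results (exit 4).
"""


class OncoprevError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OncoprevError):
    """Invalid configuration: bad panel, ambiguous synonym table, bad paths."""


class FormatError(OncoprevError):
    """Malformed input file (e.g. a MAF missing a mandatory column)."""


class IntegrityError(OncoprevError):
    """Internally inconsistent data (e.g. record sample_id outside roster)."""


class AlignmentError(OncoprevError):
    """Gene/site universes of two objects do not line up."""


class NumericError(OncoprevError):
    """Undefined numeric result (zero variance, empty cohort, all-zero table)."""


class EmptyCohortWarning(UserWarning):
    """A stratification or filter produced an empty cohort."""
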