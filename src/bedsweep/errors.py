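"""Exception hierarchy for bedsweep.

All package errors derive from :class:`BedsweepError` so callers can catch
everything with one clause; most also derive from the matching builtin
(``ValueError``/``RuntimeError``) so generic handling keeps working.
"""


class BedsweepError(Exception):
    """Base class for all bedsweep errors."""


class InvalidParameterError(BedsweepError, ValueError):
    """A scalar parameter is outside its valid domain (e.g. dose <= 0)."""


class EmptyInputError(BedsweepError, ValueError):
    """An operation received an empty cohort or empty result list."""


class DegenerateLabelsError(BedsweepError, ValueError):
    """A classification outcome contains only one class."""


class InvalidDesignError(BedsweepError, ValueError):
    """A regression design matrix is unusable (constant column, no events)."""


class UndefinedTestError(BedsweepError, ValueError):
    """A hypothesis test is undefined for the given data (e.g. no events)."""


class SchemaError(BedsweepError, ValueError):
    """A cohort file violates the documented CSV schema.

    Attributes
    ----------
    errors : list of str
        One human-readable message per offending cell, naming the row.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("cohort schema violation:\n" + "\n".join(self.errors))


class CalibrationError(BedsweepError, RuntimeError):
    """The synthetic-cohort baseline hazard cannot reach the target incidence."""
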