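"""Exception hierarchy shared across the package."""


class TriageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TriageError):
    """A configuration document is invalid; the message names the offending field."""


class MissingDataError(TriageError):
    """A variable required by a criterion or estimator is absent from the record."""


class UndefinedMetricError(TriageError):
    """A 2x2 margin is empty so the requested metric is undefined."""


class CaseCohortPPVWarning(UserWarning):
    """Positive predictive value requested from a case-enriched 2x2 table.

    Under case-cohort sampling the column margins of the table do not reflect
    population prevalence, so tp/(tp+fp) over-states the predictive value.
    Use a likelihood ratio combined with the sub-cohort prevalence instead.
    """
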