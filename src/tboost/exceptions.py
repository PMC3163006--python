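"""Exception hierarchy shared across the package.

Errors are split into what a user can fix in their invocation
(:class:`ConfigurationError`), what is wrong with the data itself
(:class:`DataError`), and states the algorithm cannot proceed from
(:class:`DegenerateScaleError`, :class:`TrainingError`).
"""


class TboostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TboostError):
    """Invalid parameters or invocation (bad column name, k out of range...)."""


class DataError(TboostError):
    """Invalid cohort data: missing values, non-numeric cells, single-class
    cohorts, label/prediction length mismatches."""


class DegenerateScaleError(TboostError):
    """Both groups of a feature have zero variance: the t statistic is
    undefined because the pooled scale estimate is zero."""


class TrainingError(TboostError):
    """Boosting cannot start: no weak learner beats chance on round one."""
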