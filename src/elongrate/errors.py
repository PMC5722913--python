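"""Exception hierarchy used across the pipeline.

Argument errors are programming/contract violations; data errors mean the
input tables violate their schema or invariants; configuration errors mean
the run configuration is inconsistent; statistics errors mean a statistic
is undefined for the given sample.
"""


class ElongrateError(Exception):
    """Base class for all package errors."""


class ArgumentError(ElongrateError, ValueError):
    """A function argument violates its precondition."""


class DataError(ElongrateError, ValueError):
    """An input table or track violates its schema or invariants."""


class ConfigurationError(ElongrateError, ValueError):
    """The run configuration is incomplete or inconsistent."""


class StatisticsError(ElongrateError, ValueError):
    """A requested statistic is undefined for the given sample."""
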