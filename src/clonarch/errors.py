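"""Exception hierarchy shared across the pipeline."""


class ClonarchError(Exception):
    """Base class for all package errors."""


class SchemaError(ClonarchError):
    """A required column is missing or a table cannot be interpreted."""


class IntegrityError(ClonarchError):
    """Cross-table referential integrity is violated (duplicates, orphans)."""


class ParameterError(ClonarchError):
    """A parameter is outside its documented domain."""


class DegenerateDataError(ClonarchError):
    """Input is too degenerate for the requested statistic (e.g. constant VAFs)."""


class InconsistencyError(ClonarchError):
    """Mutually contradictory values within one record (e.g. CN=0 with reads)."""
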