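"""Exception hierarchy for the DCIS profiling pipeline."""


class DcisProfilerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DcisProfilerError, ValueError):
    """An invalid configuration value; message names the offending field."""


class DataError(DcisProfilerError, ValueError):
    """Malformed or inconsistent input data (missing fields, orphan ids)."""


class DegenerateDataError(DcisProfilerError, ValueError):
    """Data without the variation a transform requires (e.g. constant column)."""


class StatisticalError(DcisProfilerError, ValueError):
    """A statistical routine was given too little data to be meaningful."""


class EscoreFitError(DcisProfilerError, RuntimeError):
    """Logistic fit failed to converge (typically complete separation)."""
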