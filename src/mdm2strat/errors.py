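"""Exception types shared across the pipeline."""


class Mdm2StratError(Exception):
    """Base class for all package errors."""


class QCFailure(Mdm2StratError):
    """Raised when an assay-level QC precondition fails (e.g. vehicle wells
    with non-positive mean cell count). Callers route this to the
    poor-growth exclusion category."""


class ValidationError(Mdm2StratError):
    """Raised for malformed inputs: inconsistent fixture specs, bad TSV
    schemas, non-positive doses, and similar user errors."""
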