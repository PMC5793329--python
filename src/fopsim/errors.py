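"""Exception hierarchy for the pipeline."""


class FopsimError(Exception):
    """Base class for all package errors."""


class DataError(FopsimError):
    """A data file or table violates the schema or an invariant."""


class CriteriaError(FopsimError):
    """A criteria configuration is malformed or inconsistent."""


class PipelineError(FopsimError):
    """A pipeline stage failed; carries stage context in the message."""
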