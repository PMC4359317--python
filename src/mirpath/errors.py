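"""Exception hierarchy shared across the pipeline."""


class MirpathError(Exception):
    """Base class for all package errors."""


class FormatError(MirpathError):
    """A file does not conform to its expected tabular format."""


class ValidationError(MirpathError):
    """In-memory data violate a type invariant or operation precondition."""


class PipelineError(MirpathError):
    """A pipeline stage cannot proceed (e.g. empty intermediate result)."""
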