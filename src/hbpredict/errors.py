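"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A config object or option combination is invalid."""


class FormatError(ValueError):
    """An on-disk cohort file is malformed; message carries the line number."""


class UnfillableColumnError(ValueError):
    """A column has no observed values to impute from; message names it."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""
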