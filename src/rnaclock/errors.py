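"""Exception types shared across the pipeline."""


class RnaClockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RnaClockError, ValueError):
    """Malformed input table (ragged rows, duplicate ids, negative counts...)."""


class ConfigError(RnaClockError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(RnaClockError, ValueError):
    """Semantically invalid value (e.g. negative age)."""


class PreconditionError(RnaClockError, ValueError):
    """Operation called on inputs that violate its preconditions."""


class SingletonBatchError(PreconditionError):
    """Batch correction requested with a batch of fewer than two samples."""

    def __init__(self, batches):
        self.batches = list(batches)
        super().__init__(
            "batch correction requires >=2 samples per batch; singleton "
            f"batch(es): {', '.join(map(str, self.batches))}"
        )


class GeneMismatchError(PreconditionError):
    """New data share too few genes with the reference, or model genes missing."""
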