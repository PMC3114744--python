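"""Exception hierarchy for metalign."""


class MetalignError(Exception):
    """Base class for all metalign errors."""


class InvalidInputError(MetalignError, ValueError):
    """A caller-supplied value violates a documented precondition."""


class FormatError(MetalignError, ValueError):
    """A file does not conform to the expected on-disk format."""


class InternalConsistencyError(MetalignError):
    """An internal invariant was violated (indicates a bug or corrupt state)."""


class BackendError(MetalignError, RuntimeError):
    """An aligner backend failed or returned an invalid alignment."""


class SchedulingError(MetalignError, RuntimeError):
    """The job executor detected an invalid job graph."""


class InfeasibleError(MetalignError, ValueError):
    """No valid decomposition exists under the given size cap."""
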