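"""Exception hierarchy shared across the package."""


class OsteosegError(Exception):
    """Base class for all package errors."""


class FormatError(OsteosegError):
    """An on-disk artefact has an unsupported layout, bit depth or size."""


class DomainError(OsteosegError):
    """An argument violates a documented precondition."""


class TrainingError(OsteosegError):
    """The supervision provided cannot train a classifier."""


class GenerationError(OsteosegError):
    """A synthetic scene could not be realised within the retry budget."""


class ModelIOError(OsteosegError):
    """A classifier model file is corrupt or version-incompatible."""
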