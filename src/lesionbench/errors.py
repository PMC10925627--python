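"""Exception hierarchy for the benchmark pipeline.

Every failure mode that a caller can act on gets its own class; generic
``ValueError`` is reserved for plain argument-contract violations.
"""


class LesionBenchError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(LesionBenchError):
    """An input is structurally valid but carries no usable signal
    (constant image, empty mask, empty ground-truth set)."""


class GeometryError(LesionBenchError):
    """An image's shape cannot be standardized to the target geometry."""


class GenerationExhaustedError(LesionBenchError):
    """The lesion-bank quota was not met within the noise-image budget."""


class PlacementExhaustedError(LesionBenchError):
    """Rejection sampling could not place all lesions within the attempt cap."""


class IntegrityError(LesionBenchError):
    """A dataset directory fails checksum or manifest consistency checks."""
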