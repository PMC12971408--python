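"""Exception hierarchy shared across the pipeline stages."""


class MuzzleIdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MuzzleIdError):
    """Invalid configuration value (unknown species, bad tier mix, ...)."""


class GenerationError(MuzzleIdError):
    """Synthetic rendering failed (degenerate geometry, bad size, ...)."""


class AnnotationFormatError(MuzzleIdError):
    """Annotation file violates the expected dialect or invariants."""


class PreprocessingError(MuzzleIdError):
    """Input image cannot be canonicalized."""


class MatcherContractError(MuzzleIdError):
    """An external matcher violated the adapter contract."""


class PairGenerationError(MuzzleIdError):
    """Pair set cannot be constructed from the given manifest."""


class CalibrationError(MuzzleIdError):
    """Threshold calibration is impossible (no imposter scores)."""


class EvaluationError(MuzzleIdError):
    """Pair evaluation encountered records it must not score."""
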