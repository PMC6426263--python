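"""Exception hierarchy shared across the pipeline."""


class SweepscanError(Exception):
    """Base class for all package errors."""


class FormatError(SweepscanError):
    """Malformed input file (duplicate positions, bad fields, ...)."""


class PhasingError(SweepscanError):
    """Phased haplotypes were required but the input is not fully phased."""


class ConfigurationError(SweepscanError):
    """Invalid or incomplete run configuration."""


class EstimationError(SweepscanError):
    """An estimator is undefined for the given input (e.g. monomorphic data)."""


class ModelError(SweepscanError):
    """Demographic model is inconsistent (e.g. lineages cannot find a common ancestor)."""


class UnsupportedFeatureError(SweepscanError):
    """An ms flag or feature outside the supported dialect."""
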