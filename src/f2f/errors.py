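"""Exception hierarchy for the f2f pipeline."""


class F2FError(Exception):
    """Base class for all f2f errors."""


class ParameterError(F2FError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class GenerationError(F2FError):
    """Synthetic scene generation failed (e.g. geometry cannot be satisfied)."""


class RegistrationError(F2FError):
    """Bead registration failed (too few or degenerate correspondences)."""


class InputError(F2FError):
    """An input file or array does not meet the pipeline contract."""


class EstimationError(F2FError):
    """Distance estimation failed (degenerate data or non-convergence)."""
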