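"""Exception hierarchy shared across the package."""


class RelkinError(Exception):
    """Base class for all package-specific errors."""


class InsufficientData(RelkinError):
    """Too few usable observations to fit (or even linearize) a model."""


class DegenerateDesign(RelkinError):
    """Design matrix is rank deficient (e.g. all predictor values equal)."""


class BootstrapFailed(RelkinError):
    """Every bootstrap replicate was degenerate; no summary can be formed."""
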