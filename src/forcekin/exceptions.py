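"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range (e.g. negative rate)."""


class FitInputError(ValueError):
    """Input data are insufficient or degenerate for the requested fit."""


class CorrectionError(ValueError):
    """Non-specific correction refused: the bin is dominated by background."""
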