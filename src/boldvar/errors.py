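"""Exception types shared across the package."""


class SpecValidationError(ValueError):
    """A generator or run specification failed validation.

    The message always names the offending field.
    """


class DegenerateDesignError(ValueError):
    """A regression design matrix is rank deficient or a predictor is constant."""
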