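"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input value violates a documented precondition.

    The message names the offending field so callers (and the CLI) can
    surface actionable feedback.
    """


class ApplicabilityError(ValidationError):
    """A request falls outside the calculator's stated range of applicability.

    The regression engine was calibrated for creatinine clearances of
    25-255 mL/min; outside that range the tool refuses rather than
    extrapolates.
    """
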