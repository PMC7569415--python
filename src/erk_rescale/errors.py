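"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented invariant; the message names it."""


class CalibrationRangeError(ValueError):
    """A signal or fraction falls outside the calibrated band."""


class RankDeficiencyError(ValueError):
    """A fit cannot be identified from the provided points."""


class DependencyError(RuntimeError):
    """A pipeline stage was asked to run before the stage it depends on."""
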