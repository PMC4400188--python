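"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class NoSignalError(RuntimeError):
    """A signal-dependent step (e.g. pyruvate appearance detection) found no signal."""


class FitError(RuntimeError):
    """A model fit failed in a way that cannot be expressed as a flagged result."""
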