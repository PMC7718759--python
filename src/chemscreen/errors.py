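"""Exception types shared across the pipeline."""


class InvalidInputError(ValueError):
    """Raised when an input table, curve or argument violates a precondition."""


class DegeneratePlateError(ValueError):
    """Raised when a plate has zero spread in fitness and cannot be Z-normalized.

    Degenerate plates are flagged rather than silently zeroed: callers catch
    this error and mark every record on the plate as excluded.
    """
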