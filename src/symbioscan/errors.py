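"""Shared exception types."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically degenerate.

    Examples: a sequence consisting only of N bases (GC undefined), or a
    zero-variance vector handed to a rank correlation.
    """
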