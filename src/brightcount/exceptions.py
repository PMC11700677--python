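"""Exception types shared across brightcount modules."""


class ValidationError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Input is too small or too degenerate for the requested operation
    (fewer than 3 non-collinear seeds, fewer than 9 tiles, ...)."""


class EmptyClassError(RuntimeError):
    """A tile class referenced by an operation contains no tiles."""


class PackingError(RuntimeError):
    """The synthetic renderer could not place the requested number of
    cells at the required minimum separation."""


class NoValidCombinationError(RuntimeError):
    """Every parameter combination in a grid search was degenerate.

    Carries per-combination failure reasons in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
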