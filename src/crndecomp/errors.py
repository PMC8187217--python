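"""Exception hierarchy."""


class CRNError(Exception):
    """Base class for all crndecomp errors."""


class CRNParseError(CRNError):
    """Malformed reaction-list input; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class ValidationError(CRNError):
    """A network or distribution violates a structural invariant."""


class ClosureError(CRNError):
    """A state-space operation required a closed component but found a leak."""


class RefusalError(CRNError):
    """Product-form assembly refused: the proportionality hypothesis on the
    shared-species functions does not hold."""


class UndecomposableError(CRNError):
    """No decomposition with solvable parts was found and no fallback applies."""
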