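"""Package-wide exception types."""


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class EstimationError(RuntimeError):
    """An estimation routine failed to converge or the design is degenerate.

    Carries optional diagnostics in ``.diagnostics`` (dict).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
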