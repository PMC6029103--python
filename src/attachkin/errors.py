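"""Exception hierarchy."""


class ParameterError(ValueError):
    """A numeric parameter is outside its admissible range."""


class StructuralError(ValueError):
    """Input records are structurally inconsistent (grids, links, shapes)."""


class FitError(RuntimeError):
    """All optimisation starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
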