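"""Exception hierarchy shared across the toolkit."""


class OmexError(Exception):
    """Base class for all toolkit errors."""


class ParseError(OmexError):
    """Syntax error in a DSL source, with best-effort location info."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {column}" if column is not None else "") + ")"
        super().__init__(message + loc)


class ValidationError(OmexError):
    """Semantic error: dangling references, duplicate ids, bad values."""


class UnsupportedFeatureError(OmexError):
    """A recognized construct that the supported subset deliberately excludes.

    ``feature`` names the construct (e.g. "algebraic rule", "event delay").
    """

    def __init__(self, feature: str, detail: str = ""):
        self.feature = feature
        msg = f"unsupported feature: {feature}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ArchiveError(OmexError):
    """Malformed OMEX container or manifest."""


class EngineError(OmexError):
    """Simulation failure (integrator breakdown, negative propensity, ...)."""


class SteadyStateError(EngineError):
    """Steady-state solver failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)
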