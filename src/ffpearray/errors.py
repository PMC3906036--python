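"""Exception hierarchy shared across the package."""


class FFPEArrayError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FFPEArrayError):
    """A configuration object or pipeline request is invalid."""


class ValidationError(FFPEArrayError):
    """An input object violates a documented invariant."""


class ConsistencyError(FFPEArrayError):
    """Internal cross-references between objects do not line up."""


class DegenerateDensityError(FFPEArrayError):
    """Background-parameter estimation received a degenerate intensity vector."""


class ParseError(FFPEArrayError):
    """A text file could not be parsed.

    Carries the offending line number (1-based) when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
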