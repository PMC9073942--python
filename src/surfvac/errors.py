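"""Exception hierarchy."""


class SurfvacError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SurfvacError):
    """Bad user configuration (unknown preset, unknown key, ...)."""


class ValidationError(SurfvacError, ValueError):
    """A value violates a documented precondition or invariant."""


class SimulationError(SurfvacError, RuntimeError):
    """The sampler failed at run time (e.g. divergent trajectory)."""


class ParseError(SurfvacError, ValueError):
    """Malformed HILLS/COLVAR/FES text input.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:"
        if line is not None:
            loc = f"{loc}{line}: "
        elif loc:
            loc = f"{loc} "
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line
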