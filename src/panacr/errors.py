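"""Exception hierarchy shared across the package."""


class PanACRError(Exception):
    """Base class for all package errors."""


class UsageError(PanACRError, ValueError):
    """A parameter was outside its documented range."""


class FormatError(PanACRError, ValueError):
    """A malformed on-disk record.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class ValidationError(PanACRError, ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


class ConfigurationError(PanACRError, ValueError):
    """A simulation or run configuration is infeasible or out of range."""


class IntegrityError(PanACRError, RuntimeError):
    """An internal invariant was violated (indicates a bug or corrupt input)."""
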