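"""Exception hierarchy.

Readers and stages raise rather than coerce: a malformed row aborts with
the file, line and field that caused it, so that silent data corruption
cannot propagate into the burden statistics.
"""


class TinvarError(Exception):
    """Base class for all package errors."""


class ConfigError(TinvarError):
    """Invalid configuration (thresholds out of domain, bad simulation parameters)."""


class FormatError(TinvarError):
    """Malformed input file. Carries file/line context where available."""

    def __init__(self, message: str, path=None, line=None, field=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if line is not None:
            ctx.append(f"line={line}")
        if field is not None:
            ctx.append(f"field={field}")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)
        self.path, self.line, self.field = path, line, field


class ValidationError(TinvarError):
    """Well-formed input with values outside the documented domain."""

    def __init__(self, message: str, path=None, line=None, field=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if line is not None:
            ctx.append(f"line={line}")
        if field is not None:
            ctx.append(f"field={field}")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)
        self.path, self.line, self.field = path, line, field


class CapabilityError(TinvarError):
    """The input lacks a capability the operation needs (e.g. per-sample genotypes)."""
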