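"""Exception types shared across the pipeline."""


class PPCPScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(PPCPScreenError):
    """An input table violates the expected schema.

    Carries enough context (file, column, row) for the CLI to point the user
    at the offending cell.
    """

    def __init__(self, message: str, *, source: str | None = None,
                 column: str | None = None, row: int | None = None):
        loc = []
        if source is not None:
            loc.append(f"file={source!r}")
        if column is not None:
            loc.append(f"column={column!r}")
        if row is not None:
            loc.append(f"row={row}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.source = source
        self.column = column
        self.row = row


class ConfigError(PPCPScreenError):
    """Invalid pipeline or generator configuration."""
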