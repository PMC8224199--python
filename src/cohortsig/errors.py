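"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input table, metadata frame, or configuration violates an invariant."""


class TableFormatError(ValidationError):
    """A TSV file could not be parsed into a valid table."""


class DegenerateFitError(RuntimeError):
    """A per-feature model could not be fit (e.g. zero-variance response)."""
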