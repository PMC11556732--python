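"""Exception types shared across the package."""


class CoraltraceError(Exception):
    """Base class for package-specific errors."""


class SchemaError(CoraltraceError, ValueError):
    """An input table is missing required columns or is internally inconsistent."""


class DegenerateDataError(CoraltraceError, ValueError):
    """Input is structurally valid but carries no usable information
    (e.g. an all-zero spectrum, a sample with zero median intensity)."""
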