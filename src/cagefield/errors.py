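"""Exception hierarchy.

All package errors derive from :class:`CageFieldError` so callers (and the
CLI) can distinguish data problems (exit code 1) from configuration
problems (exit code 2) with two except clauses.
"""


class CageFieldError(Exception):
    """Base class for all package errors."""


class FormatError(CageFieldError):
    """A file did not conform to its declared dialect (parse/format error)."""


class StructureError(CageFieldError):
    """Structurally inconsistent data (e.g. atom-count mismatch across frames)."""


class SelectionError(CageFieldError):
    """A selection expression failed to parse or referenced unknown labels."""


class GeometryError(CageFieldError):
    """Degenerate geometry (coincident atoms, collinear axis references, ...)."""


class SingularityError(CageFieldError):
    """A field probe point coincides with a source charge."""


class ParameterError(CageFieldError):
    """An out-of-range or inconsistent parameter value."""


class ConfigError(CageFieldError):
    """An invalid run configuration (caught before any computation starts)."""
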