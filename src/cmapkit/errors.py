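"""Exception hierarchy for cmapkit.

All package-specific errors derive from :class:`CmapError` so callers can
catch one base class at pipeline boundaries (e.g. the CLI batch loop).
"""


class CmapError(Exception):
    """Base class for all cmapkit errors."""


class ParseError(CmapError):
    """A text file could not be parsed; message names the offending line/cell."""


class StructureError(CmapError):
    """File parsed but its shape is inconsistent (sweep lengths, column count)."""


class MetadataConflictError(CmapError):
    """On-disk data contradicts the recording metadata (e.g. time column vs rate)."""


class ConfigError(CmapError):
    """Invalid metadata or simulation configuration."""


class DetectionError(CmapError):
    """Automatic stimulus-artifact detection found no candidate onset."""


class DegenerateDataError(CmapError):
    """Statistical input is degenerate (e.g. zero variance with unequal means)."""
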