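"""Exception hierarchy shared across the package."""


class SurfChannelError(Exception):
    """Base class for all package-specific errors."""


class PdbParseError(SurfChannelError):
    """A PDB line could not be parsed; message carries the line number."""


class StructureError(SurfChannelError):
    """Inconsistent structure/trajectory, e.g. atom-count mismatch between models."""


class PdbFormatError(SurfChannelError):
    """A value cannot be represented in fixed-width PDB columns."""


class SchemaError(SurfChannelError):
    """Tabular input/output does not match the expected schema."""


class TableParseError(SurfChannelError):
    """A table cell could not be parsed; message carries the row number."""


class SelectionError(SurfChannelError):
    """An atom selection is invalid or matches nothing."""


class AlignmentError(SurfChannelError):
    """Superposition impossible (degenerate or collinear fit set)."""


class LabellingError(SurfChannelError):
    """A substrate atom is missing the labels downstream stages require."""


class SiteDefinitionError(SurfChannelError):
    """An active-site definition selects no anchor atoms."""


class ParameterError(SurfChannelError):
    """A numeric parameter is out of its valid range."""


class SpecError(SurfChannelError):
    """A synthetic-system specification is internally inconsistent."""


class ConfigError(SurfChannelError):
    """A pipeline configuration file is missing required keys or malformed."""
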