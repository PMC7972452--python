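"""Exception hierarchy for lineage parsing, alignment, and analysis."""


class Lineage4dError(Exception):
    """Base class for all package errors."""


class FormatError(Lineage4dError):
    """A file does not conform to the expected tabular layout."""


class StructureError(Lineage4dError):
    """Parent/daughter links or track topology are inconsistent."""


class DuplicationError(Lineage4dError):
    """Duplicate (embryo, cell, frame) rows in an input table."""


class NamingError(Lineage4dError):
    """A cell name cannot be resolved under Sulston nomenclature."""


class ConfigurationError(Lineage4dError):
    """Missing or invalid configuration (e.g. absent pixel calibration)."""


class AlignmentError(Lineage4dError):
    """Temporal alignment cannot be performed (e.g. ABa division absent)."""


class AxisError(Lineage4dError):
    """Embryonic axes cannot be inferred (e.g. no MS-lineage cells)."""


class InsufficientLandmarkError(Lineage4dError):
    """Too few shared named cells for a Procrustes superposition."""


class GeometryError(Lineage4dError):
    """Simulated cells cannot be packed inside the configured eggshell."""


class ArgumentError(Lineage4dError):
    """An operation was called with an unsupported argument value."""


class LookupError_(Lineage4dError):
    """A cell was queried that is absent from the reference model."""
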