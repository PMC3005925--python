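"""Exception hierarchy for opergate.

Every failure mode a caller may want to catch has its own class; all inherit
from :class:`OpergateError` so a CLI can trap the lot in one place.
"""


class OpergateError(Exception):
    """Base class for all opergate errors."""


class SequenceAlphabetError(OpergateError, ValueError):
    """A sequence contains characters outside the strict A/C/G/T alphabet."""


class AnnealingError(OpergateError, ValueError):
    """Two oligos cannot be annealed into a clean duplex."""


class AmbiguousAlignmentError(AnnealingError):
    """More than one valid ungapped antiparallel alignment exists."""


class UnsupportedEndError(OpergateError, ValueError):
    """An operation met a 3' overhang or otherwise unsupported end kind."""


class LigationError(OpergateError, ValueError):
    """Adjacent fragment ends are incompatible at a named joint."""


class OrientationError(OpergateError, ValueError):
    """An insert fits a cut backbone in zero or two orientations."""


class AmbiguousSiteError(OpergateError, ValueError):
    """A backbone enzyme has more than one site where the standard requires one."""


class DesignError(OpergateError, ValueError):
    """A part design request violates the part standard (forbidden site etc.)."""


class StandardViolationError(OpergateError, ValueError):
    """A platform or part offered to a standardized operation does not conform."""


class MetadataError(OpergateError, ValueError):
    """An annotation is missing required regulator/promoter metadata."""


class GenerationError(OpergateError, RuntimeError):
    """Seeded sequence generation failed to satisfy constraints within bounds."""


class ParseError(OpergateError, ValueError):
    """A sequence or configuration file could not be parsed."""


class GateSizeError(OpergateError, ValueError):
    """A truth-table request exceeds the combinatorial guard (more than 8 inputs)."""
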