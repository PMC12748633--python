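"""Exception hierarchy for phasedig.

All package-specific failures derive from :class:`PhaseDigError` so callers
can catch one base class; most also derive from the closest builtin
(``ValueError`` etc.) so generic handling keeps working.
"""


class PhaseDigError(Exception):
    """Base class for all phasedig errors."""


class VocabularyError(PhaseDigError, KeyError):
    """An unknown phase-state code was used."""


class ArityError(PhaseDigError, ValueError):
    """More than two phase labels were combined into one state."""


class NotEnclosedError(PhaseDigError, ValueError):
    """The diagram image contains no closed plot frame."""


class GeometryError(PhaseDigError, ValueError):
    """Degenerate geometry (e.g. collinear quadrilateral corners)."""


class EditError(PhaseDigError, ValueError):
    """An edit primitive could not be applied."""


class SnapError(PhaseDigError, ValueError):
    """A guide point could not be snapped to the drawing."""


class RoutingError(PhaseDigError, ValueError):
    """No fewest-steps path exists between two snapped guide points."""


class RangeError(PhaseDigError, ValueError):
    """A data coordinate lies outside the calibrated axis range."""


class NoRegionsError(PhaseDigError, ValueError):
    """A mask contains no interior (white) pixels to label."""


class NoAssignablePhaseError(PhaseDigError, ValueError):
    """Every phase probability fell below the cutoff; the row cannot be normalized."""


class SchemaError(PhaseDigError, ValueError):
    """A PhDat record or dataset violates the record format."""


class MappingError(PhaseDigError, ValueError):
    """The region-to-state mapping does not cover every labeled region."""
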