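"""Exception hierarchy for tmdock.

Every anticipated failure mode raises a subclass of :class:`TmdockError`,
so callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class TmdockError(Exception):
    """Base class for all tmdock errors."""


class EmptyStructureError(TmdockError):
    """A structure contains no atoms after parsing/filtering."""


class CongruenceError(TmdockError):
    """Ensemble frames do not share one atom topology."""


class SelectionError(TmdockError):
    """An atom/residue selection matched nothing."""


class PdbFormatError(TmdockError):
    """Coordinates or fields cannot be represented in fixed-column PDB."""


class UnsupportedDialectError(TmdockError):
    """An OpenDX file uses a grid layout this package does not support."""


class MapParseError(TmdockError):
    """An OpenDX file could not be parsed at all."""


class LevelSetError(TmdockError):
    """Requested isovalue lies outside the map's value range."""


class AxisError(TmdockError):
    """A rotation axis is degenerate (zero length)."""


class EvaluationError(TmdockError):
    """The docking objective returned a non-finite value.

    Carries the offending pose in ``.pose``.
    """

    def __init__(self, message, pose=None):
        super().__init__(message)
        self.pose = pose


class DegenerateReferenceError(TmdockError):
    """The reference complex has no contacts / no interface."""


class DegenerateSuperpositionError(TmdockError):
    """Point sets too small or collinear for a unique superposition."""


class CorrespondenceError(TmdockError):
    """Model and reference atom selections do not correspond 1:1."""
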