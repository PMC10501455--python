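"""Exception hierarchy for dentamorph.

All errors raised by the toolkit derive from :class:`DentamorphError`, so
callers can catch one base class at pipeline boundaries.
"""


class DentamorphError(Exception):
    """Base class for all dentamorph errors."""


class FormatError(DentamorphError, ValueError):
    """An input file is not in the expected format (e.g. non-3D NIfTI)."""


class GeometryError(DentamorphError, ValueError):
    """Two volumes that must share a grid (shape, spacing, origin) do not."""


class ParameterError(DentamorphError, ValueError):
    """A parameter violates its documented bounds or invariants."""


class DegenerateShapeError(DentamorphError, ValueError):
    """A point cloud or mask is too degenerate for the requested analysis
    (e.g. rank-deficient covariance for PCA)."""


class StageError(DentamorphError, RuntimeError):
    """A composite pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
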