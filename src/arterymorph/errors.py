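"""Exception types raised across the pipeline."""


class ArteryMorphError(Exception):
    """Base class for pipeline errors."""


class SizingError(ArteryMorphError, ValueError):
    """Requested phantom geometry does not fit the rendered frame."""


class OverlapBudgetError(ArteryMorphError, RuntimeError):
    """Requested nuclei density cannot be met with disjoint blobs."""


class LumenLeakError(ArteryMorphError, RuntimeError):
    """Flood fill escaped the lumen (seed likely on wall tissue)."""


class ContourError(ArteryMorphError, ValueError):
    """Perivascular contour is not a closed polygon."""


class DegenerateInputError(ArteryMorphError, ValueError):
    """A mask or table required by an operation is empty."""


class InconsistencyError(ArteryMorphError, ValueError):
    """Layer measurements contradict each other beyond tolerance."""


class CalibrationLookupError(ArteryMorphError, KeyError):
    """No threshold calibration registered for a batch key."""


class GridError(ArteryMorphError, ValueError):
    """Dose grids differ across vessels that are being summarized."""


class DesignError(ArteryMorphError, ValueError):
    """Invalid study design (duplicate groups, single-level factor)."""


class JoinError(ArteryMorphError, ValueError):
    """Cohort tables cannot be joined on the (condition, week, animal) key."""
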