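"""Exception hierarchy for sampenmap.

Every error raised by the public API derives from :class:`SampenMapError`
so callers can catch the package's failures with one clause.
"""


class SampenMapError(Exception):
    """Base class for all sampenmap errors."""


class GridMismatchError(SampenMapError):
    """Two lattices that must share a 3D grid do not."""


class ShortSeriesError(SampenMapError):
    """Series too short: the (m+1)-window needs N >= m + 2."""


class InvalidSeriesError(SampenMapError):
    """Series contains non-finite values."""


class BadLengthError(SampenMapError):
    """Requested truncation length exceeds the series."""


class DuplicateScanError(SampenMapError):
    """Two scans share (subject_id, condition, scan_index)."""


class UnknownClassError(SampenMapError):
    """ROI class not present in the atlas column metadata."""


class ConstantInputError(SampenMapError):
    """Correlation requested on a constant series."""


class TooFewScansError(SampenMapError):
    """Fewer than three scans available for a correlation matrix."""


class TooFewSubjectsError(SampenMapError):
    """ICC needs at least three subjects."""


class SubjectMismatchError(SampenMapError):
    """Scan-1 and scan-2 tables do not cover the same subjects."""


class UnbalancedDesignError(SampenMapError):
    """Two-factor ANOVA requires a balanced, fully crossed design."""


class NonstationaryPhiError(SampenMapError):
    """AR(1) coefficient outside (-1, 1)."""


class GridTooSmallError(SampenMapError):
    """Parcel voxel counts exceed the grid volume."""


class OutOfRangeError(SampenMapError):
    """Probability outside [0, 1]."""


class MissingInputError(SampenMapError):
    """A pipeline stage input file is absent."""
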