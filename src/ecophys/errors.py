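"""Named failure modes shared across the package.

Each error corresponds to a distinct precondition violation so callers can
react to (or test for) the specific way an input was malformed, rather than
catching a generic ValueError.
"""


class EcophysError(ValueError):
    """Base class for all input-validation failures in this package."""


class TooFewPointsError(EcophysError):
    """A growth curve has fewer points than the sliding window needs."""


class NonPositiveDensityError(EcophysError):
    """Cell densities must be strictly positive (log2 is taken)."""


class DuplicateTimesError(EcophysError):
    """Zero time variance within a regression window (repeated times)."""


class RadiusAreaError(EcophysError):
    """A measured radius is inconsistent with the segmented area (S < pi*r^2)."""


class AllRadiiInvalidError(EcophysError):
    """Every radius of a cell fails the S >= pi*r^2 consistency check."""


class EmptyInputError(EcophysError):
    """An aggregation was called on an empty collection."""


class MixingRangeError(EcophysError):
    """A salinity target lies outside the two mixing endpoints."""


class RecruitmentTableError(EcophysError):
    """A recruitment count table violates its invariants."""


class ANIMatrixError(EcophysError):
    """A pairwise identity matrix is not square/valid."""


class InsufficientSamplesError(EcophysError):
    """Too few complete (abundance, environment) pairs for a correlation."""
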