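"""Exception hierarchy shared across the package."""


class StanceKinError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(StanceKinError):
    """Coincident landmarks make an angle undefined."""


class InsufficientDataError(StanceKinError):
    """Too few observations (or stance events) to compute a quantity."""


class UndefinedIndexError(StanceKinError):
    """A ratio index (AUI, relative JAE) with a non-positive denominator."""


class MissingLandmarkError(StanceKinError):
    """A mapped marker is absent at a required event frame."""

    def __init__(self, marker: str, frame: int):
        self.marker = marker
        self.frame = frame
        super().__init__(f"marker {marker!r} missing at frame {frame}")


class MissingDataError(StanceKinError):
    """A required value (e.g. one limb's AUI) is missing."""


class DegenerateVarianceError(StanceKinError):
    """A group has zero within-group variance where variance is required."""


class DegenerateRanksError(StanceKinError):
    """All observations tied; rank-based statistics undefined."""


class InvalidProbabilityError(StanceKinError):
    """A p-value or level outside [0, 1]."""


class IncompleteDesignError(StanceKinError):
    """Missing cells in a ratings matrix where a complete design is required."""


class NewickParseError(StanceKinError):
    """Malformed Newick input; carries an approximate position when known."""


class NameMismatchError(StanceKinError):
    """Requested tip labels not present in the tree."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"labels not in tree: {', '.join(self.missing)}")


class SingularityError(StanceKinError):
    """Singular covariance or collinear design in a GLS fit."""


class ConfigError(StanceKinError):
    """Invalid or infeasible configuration."""
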