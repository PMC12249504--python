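"""Exception hierarchy for the planning pipeline."""


class MandrecError(Exception):
    """Base class for all planning errors."""


class MeshLoadError(MandrecError):
    """A mesh file could not be loaded or is unusable (empty, non-manifold)."""


class LandmarkError(MandrecError):
    """Malformed landmark data (duplicate or unknown names, bad coordinates)."""


class InsufficientLandmarksError(MandrecError):
    """Fewer corresponding landmark pairs than the registration minimum."""


class DegenerateGeometryError(MandrecError):
    """Geometrically degenerate configuration (coplanar controls, zero axis)."""


class CutPlacementError(MandrecError):
    """A resection cut cannot be placed or does not intersect the bone."""


class UnconstructibleScenarioError(MandrecError):
    """A requested defect scenario cannot be realized on the given mandible."""


class InfeasibleChainError(MandrecError):
    """No segment chain satisfies the length constraints."""


class HarvestLengthError(MandrecError):
    """The donor fibula is too short for the requested segments."""

    def __init__(self, message: str, shortfall_mm: float = 0.0):
        super().__init__(message)
        self.shortfall_mm = float(shortfall_mm)


class ConfigError(MandrecError):
    """Invalid engine configuration."""


class WorkflowError(MandrecError):
    """Pipeline steps invoked out of order or with missing artifacts."""
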