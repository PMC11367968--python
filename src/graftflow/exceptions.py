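"""Exception hierarchy."""


class GraftFlowError(Exception):
    """Base class for all graftflow errors."""


class GeometryError(GraftFlowError):
    """Invalid geometry specification."""


class OcclusionError(GeometryError):
    """A deformation would close the lumen completely."""


class ResolutionError(GraftFlowError):
    """Grid resolution too coarse to represent the geometry."""


class SolverError(GraftFlowError):
    """Flow solver failure."""


class CflError(SolverError):
    """Advective stability (CFL) bound violated during a run."""


class NumericsError(SolverError):
    """Non-finite values detected in the solution fields."""


class PlaneError(GraftFlowError):
    """Measurement-plane placement failure."""


class ZeroVarianceError(GraftFlowError):
    """Correlation requested on a constant sample (undefined R)."""


class IncompleteSweepError(GraftFlowError):
    """Statistical analysis requested on an incomplete severity x flow sweep."""


class ConfigError(GraftFlowError):
    """Invalid run configuration."""
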