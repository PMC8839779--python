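"""Exception hierarchy for the thermostress pipeline."""


class ThermoStressError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(ThermoStressError):
    """A cohort or stage configuration violates its invariants."""


class DegenerateGeometryError(ThermoStressError):
    """Fiducial geometry too degenerate for affine estimation."""


class StreamSyncError(ThermoStressError):
    """RGB and IR streams do not overlap in time."""


class FaceNotFoundError(ThermoStressError):
    """Temperature thresholding produced an empty face mask."""


class ROIPlacementError(ThermoStressError):
    """A ROI centre landmark falls outside the segmented face."""


class UnrecoverableSignalError(ThermoStressError):
    """Signal cleaning cannot proceed (e.g. every sample an outlier)."""


class InsufficientDataError(ThermoStressError):
    """Too few samples/beats for the requested feature."""


class DecompositionError(ThermoStressError):
    """The electrodermal decomposition solver failed to converge."""


class UnusableSeriesError(ThermoStressError):
    """More than half of an RR series is flagged as artifactual."""


class CoverageGapError(ThermoStressError):
    """A beat gap too long for reliable tachogram interpolation."""


class NoSpectralPeakError(ThermoStressError):
    """No dominant spectral peak above the noise floor in band."""


class UndefinedTestError(ThermoStressError):
    """A paired test is undefined (e.g. all differences zero)."""


class RankingError(ThermoStressError):
    """SVM training failed during recursive feature elimination."""


class TableAssemblyError(ThermoStressError):
    """Feature-table assembly found mismatched or duplicate keys."""
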