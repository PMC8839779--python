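"""Per-session thermal features: Mean, Std, DMean, DStd for each ROI signal.

The derivative is the forward first difference scaled by the frame rate
(units degC/s); standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import InsufficientDataError
from .rois import ROI_LABELS, THERMAL_FEATURE_KINDS
from .thermal import ROISignal, ROISignalSet


class ThermalFeatures(NamedTuple):
    mean: float   # degC
    std: float    # degC
    dmean: float  # degC/s
    dstd: float   # degC/s


def thermal_features(signal: ROISignal | np.ndarray, fs: float) -> ThermalFeatures:
    """Mean, sample SD, and mean/sample SD of the scaled first difference."""
    values = signal.values if isinstance(signal, ROISignal) else np.asarray(signal, float)
    if len(values) < 2:
        raise InsufficientDataError("at least 2 samples required for thermal features")
    deriv = np.diff(values) * fs
    return ThermalFeatures(
        mean=float(values.mean()),
        std=float(values.std(ddof=1)),
        dmean=float(deriv.mean()),
        dstd=float(deriv.std(ddof=1)) if len(deriv) > 1 else 0.0,
    )


def thermal_feature_row(signal_set: ROISignalSet) -> dict[str, float]:
    """The 56 named thermal features for one session (ROI-major order)."""
    row: dict[str, float] = {}
    for name, sig in signal_set.signals.items():
        feats = thermal_features(sig, signal_set.fs)
        label = ROI_LABELS[name]
        for kind, value in zip(THERMAL_FEATURE_KINDS, feats):
            row[f"{label} {kind}"] = value
    return row
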