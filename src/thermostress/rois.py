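"""Facial ROI registry: canonical names, feature labels, and face-box layout.

Fourteen facial regions are monitored: the nose tip, the nasal septum,
central/right/left forehead, right/left cheek, central/right/left chin,
right/left periorbital, and right/left maxillary areas.  Each region
contributes four thermal features (Mean, Std, DMean, DStd), giving the 56
thermal columns of the feature table.
"""

from __future__ import annotations

ROI_NAMES: tuple[str, ...] = (
    "Nose",
    "Forehead",
    "R-Forehead",
    "L-Forehead",
    "R-Cheek",
    "L-Cheek",
    "N-Sept",
    "Chin",
    "R-Chin",
    "L-Chin",
    "R-POrb",
    "L-POrb",
    "R-Max",
    "L-Max",
)

#: Feature-column label for each ROI.  Lateral prefixes lose the hyphen
#: ("R-POrb" -> "RPOrb") while the nasal septum keeps it ("N-Sept"), matching
#: the conventional printed labels (e.g. "RPOrb DMean", "N-Sept DMean").
ROI_LABELS: dict[str, str] = {
    name: name if name == "N-Sept" else name.replace("-", "") for name in ROI_NAMES
}

THERMAL_FEATURE_KINDS: tuple[str, ...] = ("Mean", "Std", "DMean", "DStd")


def thermal_feature_names() -> list[str]:
    """The 56 thermal feature-column names, ROI-major order."""
    return [f"{ROI_LABELS[r]} {k}" for r in ROI_NAMES for k in THERMAL_FEATURE_KINDS]


EDA_FEATURE_NAMES: tuple[str, ...] = (
    "TonicMean",
    "TonicStd",
    "PksMax",
    "PhasicMean",
    "PhasicStd",
    "NPks",
    "PksSum",
    "EDAsymp",
)

HRV_FEATURE_NAMES: tuple[str, ...] = (
    "mean HRV",
    "std HRV",
    "RMSSD",
    "pNN50",
    "LF",
    "HF",
    "LF/HF",
    "SD1",
    "SD2",
    "SampEn",
)

RESP_FEATURE_NAMES: tuple[str, ...] = ("RESP freq",)


def all_feature_names() -> list[str]:
    """All 75 feature columns: 56 thermal + 8 EDA + 10 HRV + 1 RESP."""
    return (
        thermal_feature_names()
        + list(EDA_FEATURE_NAMES)
        + list(HRV_FEATURE_NAMES)
        + list(RESP_FEATURE_NAMES)
    )


# Layout of ROI centres inside the face bounding box, as (row, col) fractions.
# Five anatomical rows (forehead, periorbital, nose/cheek, septum/maxillary,
# chin) by up to three columns; chosen so that painted patches never overlap.
ROI_LAYOUT: dict[str, tuple[float, float]] = {
    "R-Forehead": (0.10, 0.18),
    "Forehead": (0.10, 0.50),
    "L-Forehead": (0.10, 0.82),
    "R-POrb": (0.30, 0.18),
    "L-POrb": (0.30, 0.82),
    "R-Cheek": (0.50, 0.18),
    "Nose": (0.50, 0.50),
    "L-Cheek": (0.50, 0.82),
    "R-Max": (0.70, 0.18),
    "N-Sept": (0.70, 0.50),
    "L-Max": (0.70, 0.82),
    "R-Chin": (0.90, 0.18),
    "Chin": (0.90, 0.50),
    "L-Chin": (0.90, 0.82),
}
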