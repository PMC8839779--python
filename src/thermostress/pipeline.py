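"""End-to-end orchestration: simulate -> extract -> features -> stats -> classify.

Stages communicate through plain files (multi-page TIFF for thermal stacks,
CSV for signals/features/statistics, JSON for ground truth and results) and
a run manifest listing the configuration, seed and SHA-256 digest of every
output, so that deterministic stages can be verified and skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cardioresp import cardioresp_feature_row
from .classify import (
    FEATURE_SETS,
    FeatureTable,
    filter_select,
    loso_accuracy_curve,
    svm_rfe_cbr_rank,
)
from .eda import decompose_eda, eda_features
from .errors import TableAssemblyError
from .features_thermal import thermal_feature_row
from .rois import ROI_NAMES
from .stats import compare_sessions, results_to_frame
from .synthgen import CohortConfig, EffectSizes, SessionRecord, iter_sessions
from .thermal import (
    ThermalFrameStack,
    clean_signal,
    extract_roi_signals,
    place_rois,
    segment_face,
    track_centres,
)


# ---------------------------------------------------------------------------
# per-session feature extraction

def extract_thermal_signals(
    stack: ThermalFrameStack,
    area_fraction: float = 0.02,
    t_low: float = 30.0,
    t_high: float = 38.0,
    clean_window: int = 5,
):
    """Thermal stage: segment, place ROIs, track, extract and clean."""
    face_mask = segment_face(stack.frames[0], t_low, t_high, stack.contours[0])
    landmarks0 = stack.landmarks[0]
    rois = place_rois(landmarks0, face_mask, area_fraction)
    centres = {r.name: r.centre for r in rois}
    tracks = track_centres(stack, centres)
    signal_set = extract_roi_signals(stack, rois, tracks, t_low, t_high)
    for name in ROI_NAMES:
        signal_set.signals[name] = clean_signal(signal_set.signals[name], clean_window)
    return signal_set


def compute_session_features(
    record: SessionRecord,
    duration_s: float,
    area_fraction: float = 0.02,
    hrv_unit: str = "hr",
) -> dict[str, float]:
    """All features for one session (56 thermal when frames are present,
    8 EDA, 10 HRV, 1 RESP)."""
    row: dict[str, float] = {}
    if record.thermal is not None:
        signal_set = extract_thermal_signals(record.thermal, area_fraction)
        row.update(thermal_feature_row(signal_set))
    decomp = decompose_eda(record.eda, record.fs_physio)
    row.update(eda_features(decomp, record.eda, record.fs_physio))
    row.update(
        cardioresp_feature_row(
            record.rpeak_times, record.resp, record.fs_physio, duration_s, hrv_unit
        )
    )
    return row


def compute_feature_table(config: CohortConfig, area_fraction: float = 0.02) -> FeatureTable:
    """Generate a cohort (streaming, one session in memory at a time) and
    extract its full feature table."""
    rows = []
    for record, _truth in iter_sessions(config):
        row = {"subject": record.subject, "session": record.session, "label": record.label}
        row.update(
            compute_session_features(record, config.session_duration_s, area_fraction)
        )
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


def assemble_feature_table(
    modality_frames: list[pd.DataFrame],
    labels: pd.DataFrame,
) -> FeatureTable:
    """Join per-modality feature frames on (subject, session) and attach labels.

    Every frame must carry ``subject`` and ``session`` columns with identical
    key sets; mismatches raise an error naming the offending subjects.
    """
    keys = None
    for df in modality_frames:
        k = set(zip(df["subject"], df["session"]))
        if len(k) != len(df):
            dupes = df[df.duplicated(subset=["subject", "session"])]
            raise TableAssemblyError(
                f"duplicate subject-session rows: {dupes[['subject', 'session']].values.tolist()}"
            )
        if keys is None:
            keys = k
        elif k != keys:
            offending = sorted({s for s, _ in keys ^ k})
            raise TableAssemblyError(f"modality key mismatch for subjects: {offending}")
    merged = modality_frames[0]
    for df in modality_frames[1:]:
        merged = merged.merge(df, on=["subject", "session"], validate="one_to_one")
    merged = merged.merge(labels, on=["subject", "session"], validate="one_to_one")
    cols = ["subject", "session", "label"] + [
        c for c in merged.columns if c not in ("subject", "session", "label")
    ]
    return FeatureTable(merged[cols])


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "cohort": {
        "n_subjects": 19,
        "session_duration_s": 180.0,
        "fs_thermal": 5.0,
        "fs_physio": 500.0,
        "frame_size": [64, 64],
        "seed": 0,
        "effect_preset": "default",  # default | null
    },
    "thermal": {"area_fraction": 0.02, "t_low": 30.0, "t_high": 38.0, "clean_window": 5},
    "stats": {"alpha": 0.05},
    "classify": {
        "nu": 0.5,
        "cbr_threshold": 0.7,
        "filter_alpha": 0.05,
        "mode": "pooled",
        "sets": list(FEATURE_SETS),
    },
}


def load_config(path: Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values)
    return cfg


def cohort_config_from_dict(cfg: dict, seed: int | None = None) -> CohortConfig:
    c = cfg["cohort"]
    effect = (
        EffectSizes.null() if c.get("effect_preset") == "null" else EffectSizes()
    )
    return CohortConfig(
        n_subjects=int(c["n_subjects"]),
        session_duration_s=float(c["session_duration_s"]),
        fs_thermal=float(c["fs_thermal"]),
        fs_physio=float(c["fs_physio"]),
        frame_size=tuple(c["frame_size"]),
        effect=effect,
        seed=int(c["seed"] if seed is None else seed),
    )


# ---------------------------------------------------------------------------
# run manifest & full pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(cfg: dict, seed: int) -> str:
    return hashlib.sha256(
        json.dumps({"config": cfg, "seed": seed}, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(
    config: dict | Path | None,
    outdir: Path,
    seed: int | None = None,
) -> dict:
    """Run simulate -> features -> stats -> classify; return the manifest.

    The feature-table stage is cached: when the manifest from a previous run
    records the same configuration hash and the features file's digest still
    matches, the table is reloaded instead of recomputed.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = cohort_config_from_dict(cfg, seed)
    seed = cohort_cfg.seed
    chash = _config_hash(cfg, seed)

    manifest_path = outdir / "manifest.json"
    features_path = outdir / "features.csv"
    table = None
    if manifest_path.exists() and features_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and old.get("digests", {}).get(
            "features.csv"
        ) == _sha256(features_path):
            table = FeatureTable(pd.read_csv(features_path))
    if table is None:
        table = compute_feature_table(cohort_cfg, cfg["thermal"]["area_fraction"])
        # %.17g round-trips float64: cached reloads are bit-identical
        table.data.to_csv(features_path, index=False, float_format="%.17g")
        table = FeatureTable(pd.read_csv(features_path))

    stats_results = compare_sessions(table.data, alpha=cfg["stats"]["alpha"])
    stats_df = results_to_frame(stats_results)
    stats_df.to_csv(outdir / "stats.csv", index=False)
    (outdir / "stats_summary.json").write_text(
        json.dumps(
            {
                "n_features": len(stats_df),
                "n_significant": int(stats_df["rejected"].sum()),
                "significant": stats_df.loc[stats_df["rejected"], "feature"].tolist(),
            },
            indent=2,
        )
    )

    clf = cfg["classify"]
    classification: dict[str, dict] = {}
    for feature_set in clf["sets"]:
        view = table.view(feature_set)
        filtered = filter_select(view, alpha=clf["filter_alpha"])
        ranking = svm_rfe_cbr_rank(
            filtered, nu=clf["nu"], cbr_threshold=clf["cbr_threshold"]
        )
        result = loso_accuracy_curve(
            view,
            mode=clf["mode"],
            nu=clf["nu"],
            cbr_threshold=clf["cbr_threshold"],
            filter_alpha=clf["filter_alpha"],
        )
        pd.DataFrame(
            {
                "rank": np.arange(1, len(ranking.ranking) + 1),
                "feature": ranking.ranking,
                "criterion": [ranking.criteria[f] for f in ranking.ranking],
            }
        ).to_csv(outdir / f"ranking_{feature_set}.csv", index=False)
        pd.DataFrame({"k": result.ks, "accuracy": result.accuracies}).to_csv(
            outdir / f"accuracy_curve_{feature_set}.csv", index=False
        )
        best_conf = result.confusion[result.best_k]
        (outdir / f"confusion_{feature_set}.json").write_text(
            json.dumps(
                {
                    "best_k": result.best_k,
                    "max_accuracy": result.max_accuracy,
                    "rows": ["Stroop", "Rest"],
                    "columns": ["pred_Stroop", "pred_Rest"],
                    "percent": best_conf.tolist(),
                },
                indent=2,
            )
        )
        classification[feature_set] = {
            "n_filtered": len(filtered.feature_columns),
            "best_k": result.best_k,
            "max_accuracy": result.max_accuracy,
        }

    outputs = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": cfg,
        "config_hash": chash,
        "classification": classification,
        "digests": {name: _sha256(outdir / name) for name in outputs},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
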