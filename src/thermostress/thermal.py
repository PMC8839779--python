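"""Thermal frame-stack processing: registration, segmentation, ROI signals.

The stage turns a registered facial thermal video into 14 cleaned
median-temperature time series: affine RGB-to-IR registration from fiducial
points, temperature-threshold face segmentation inside the face contour,
proportional ROI placement at landmark centres, frame-to-frame centre
tracking, per-frame ROI medians, and moving-median + 3-SD outlier cleaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from numpy.lib.stride_tricks import sliding_window_view
from skimage.draw import polygon2mask

from .errors import (
    DegenerateGeometryError,
    FaceNotFoundError,
    InsufficientDataError,
    ROIPlacementError,
    StreamSyncError,
    UnrecoverableSignalError,
)
from .rois import ROI_NAMES

# temperature band of living facial skin used for threshold segmentation
T_LOW_DEFAULT = 30.0
T_HIGH_DEFAULT = 38.0


@dataclass
class ThermalFrameStack:
    """A timed stack of temperature images with landmark metadata.

    frames: (T, H, W) temperatures in degC; timestamps in seconds, strictly
    increasing; one landmark dict (name -> (row, col)) and one face-contour
    polygon per frame.  Coordinates are 0-based (row, col).
    """

    frames: np.ndarray
    fs: float
    timestamps: np.ndarray
    landmarks: list[dict[str, tuple[float, float]]] = field(default_factory=list)
    contours: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("temperatures must be finite")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_thermal_stack(tiff_path: Path) -> ThermalFrameStack:
    """Read a multi-page float TIFF plus its JSON sidecar."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    landmarks = [
        {name: tuple(pt) for name, pt in frame_lm.items()}
        for frame_lm in sidecar.get("landmarks", [])
    ]
    contours = [np.asarray(c, dtype=float) for c in sidecar.get("contours", [])]
    return ThermalFrameStack(
        frames=frames,
        fs=float(sidecar["fs"]),
        timestamps=np.asarray(sidecar["timestamps"], dtype=float),
        landmarks=landmarks,
        contours=contours,
    )


# ---------------------------------------------------------------------------
# registration & synchronization

@dataclass
class AffineTransform:
    """2x3 matrix mapping homogeneous source points to destination points."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("affine matrix must be finite")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise DegenerateGeometryError("linear part of affine transform is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        A = self.matrix[:, :2]
        b = self.matrix[:, 2]
        Ainv = np.linalg.inv(A)
        return AffineTransform(np.column_stack([Ainv, -Ainv @ b]))


def estimate_affine(src_points: np.ndarray, dst_points: np.ndarray) -> AffineTransform:
    """Least-squares 2D affine fit from >= 3 non-collinear point pairs."""
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise DegenerateGeometryError("source and destination point sets must match, Nx2")
    if src.shape[0] < 3:
        raise DegenerateGeometryError("at least 3 point pairs required")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateGeometryError("source points are collinear")
    design = np.column_stack([src, np.ones(len(src))])
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform(sol.T)


@dataclass
class StreamPairing:
    """Nearest-timestamp RGB/IR frame pairing; unpaired IR frames flagged."""

    pairs: list[tuple[int, int]]        # (ir_index, rgb_index)
    unpaired_ir: list[int]
    max_gap_s: float


def synchronize_streams(
    rgb_timestamps: np.ndarray,
    ir_timestamps: np.ndarray,
    rgb_fs: float = 30.0,
) -> StreamPairing:
    """Pair each IR frame with its nearest RGB frame in time.

    A pairing is accepted when the nearest gap is at most half the RGB frame
    period; IR frames outside RGB coverage are flagged, never dropped
    silently.
    """
    rgb_t = np.asarray(rgb_timestamps, dtype=float)
    ir_t = np.asarray(ir_timestamps, dtype=float)
    if rgb_t[-1] < ir_t[0] or ir_t[-1] < rgb_t[0]:
        raise StreamSyncError("RGB and IR time ranges are disjoint")
    max_gap = 0.5 / rgb_fs
    idx = np.searchsorted(rgb_t, ir_t)
    pairs: list[tuple[int, int]] = []
    unpaired: list[int] = []
    worst = 0.0
    for i, t in enumerate(ir_t):
        cands = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(rgb_t)]
        j = min(cands, key=lambda j: abs(rgb_t[j] - t))
        gap = abs(rgb_t[j] - t)
        if gap <= max_gap:
            pairs.append((i, j))
            worst = max(worst, gap)
        else:
            unpaired.append(i)
    return StreamPairing(pairs=pairs, unpaired_ir=unpaired, max_gap_s=worst)


# ---------------------------------------------------------------------------
# segmentation & ROI placement

def segment_face(
    frame: np.ndarray,
    t_low: float = T_LOW_DEFAULT,
    t_high: float = T_HIGH_DEFAULT,
    contour: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean face mask: pixels strictly inside (t_low, t_high) and, when a
    face-contour polygon is given, inside it (separating face from neck and
    torso)."""
    if t_low >= t_high:
        raise ValueError("t_low must be < t_high")
    frame = np.asarray(frame, dtype=float)
    mask = (frame > t_low) & (frame < t_high)
    if contour is not None:
        poly = polygon2mask(frame.shape, np.asarray(contour, dtype=float))
        mask &= poly
    if not mask.any():
        raise FaceNotFoundError("temperature thresholding found no face pixels")
    return mask


@dataclass
class ROISpec:
    """One named facial region: centre landmark and boolean pixel mask."""

    name: str
    centre: tuple[int, int]
    area_fraction: float
    mask: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        """Mask pixel coordinates relative to the centre, (N, 2)."""
        pix = np.argwhere(self.mask)
        return pix - np.asarray(self.centre)


def _rectangle_pixels(centre: tuple[int, int], n_pixels: int) -> np.ndarray:
    """Near-square rectangle of exactly ``n_pixels`` centred on ``centre``."""
    h = max(1, round(np.sqrt(n_pixels)))
    w = int(np.ceil(n_pixels / h))
    r0 = centre[0] - (h - 1) // 2
    c0 = centre[1] - (w - 1) // 2
    rows, cols = np.meshgrid(np.arange(r0, r0 + h), np.arange(c0, c0 + w), indexing="ij")
    pix = np.column_stack([rows.ravel(), cols.ravel()])
    return pix[:n_pixels]  # trim the trailing cells of the last row


def place_rois(
    landmarks: dict[str, tuple[float, float]],
    face_mask: np.ndarray,
    area_fraction: float | dict[str, float] = 0.02,
) -> list[ROISpec]:
    """Place the 14 ROIs, each sized proportionally to the face pixel count.

    ROI pixel count = round(area_fraction x face pixels), as a near-square
    axis-aligned rectangle centred on the landmark, clipped to the face mask.
    """
    if not face_mask.any():
        raise FaceNotFoundError("face mask is empty")
    face_px = int(face_mask.sum())
    fractions = (
        {n: area_fraction for n in ROI_NAMES}
        if np.isscalar(area_fraction)
        else dict(area_fraction)
    )
    missing = [n for n in ROI_NAMES if n not in landmarks]
    if missing:
        raise ROIPlacementError(f"missing centre landmarks: {missing}")
    rois: list[ROISpec] = []
    H, W = face_mask.shape
    for name in ROI_NAMES:
        centre = (int(round(landmarks[name][0])), int(round(landmarks[name][1])))
        if not (0 <= centre[0] < H and 0 <= centre[1] < W) or not face_mask[centre]:
            raise ROIPlacementError(f"ROI centre for {name} lies outside the face mask")
        n_pix = int(round(fractions[name] * face_px))
        pix = _rectangle_pixels(centre, max(n_pix, 1))
        mask = np.zeros_like(face_mask)
        valid = (
            (pix[:, 0] >= 0) & (pix[:, 0] < H) & (pix[:, 1] >= 0) & (pix[:, 1] < W)
        )
        pix = pix[valid]
        inside = face_mask[pix[:, 0], pix[:, 1]]
        pix = pix[inside]
        if len(pix) == 0:
            raise ROIPlacementError(f"ROI {name} has no pixels inside the face mask")
        mask[pix[:, 0], pix[:, 1]] = True
        rois.append(ROISpec(name=name, centre=centre, area_fraction=fractions[name], mask=mask))
    return rois


# ---------------------------------------------------------------------------
# tracking

@dataclass
class TrackResult:
    """Per-frame integer centre tracks; lost tracks flagged with frame index."""

    tracks: dict[str, np.ndarray]        # name -> (T, 2) int
    lost: dict[str, int]                 # name -> first frame where lost


def track_centres(
    stack: ThermalFrameStack,
    initial_centres: dict[str, tuple[int, int]],
    patch_radius: int = 5,
    search_radius: int = 5,
) -> TrackResult:
    """Track ROI centres by integer-displacement block matching.

    For each frame the template is the (2r+1)^2 patch around the previous
    centre in the previous frame; the new centre minimizes the sum of squared
    differences over displacements within ``search_radius``.  Ties prefer the
    smallest displacement.  A track whose search window would leave the image
    is flagged lost at that frame and frozen.
    """
    T, H, W = stack.frames.shape
    side = 2 * patch_radius + 1
    tracks = {n: np.zeros((T, 2), dtype=int) for n in initial_centres}
    lost: dict[str, int] = {}
    for name, c in initial_centres.items():
        c = (int(round(c[0])), int(round(c[1])))
        if not (0 <= c[0] < H and 0 <= c[1] < W):
            raise ROIPlacementError(f"initial centre for {name} outside frame")
        tracks[name][0] = c

    disp = np.arange(-search_radius, search_radius + 1)
    dr, dc = np.meshgrid(disp, disp, indexing="ij")
    disp_norm = (dr**2 + dc**2).ravel()

    for t in range(1, T):
        prev = stack.frames[t - 1]
        cur = stack.frames[t]
        for name, trk in tracks.items():
            if name in lost:
                trk[t] = trk[t - 1]
                continue
            r, c = trk[t - 1]
            r0, r1 = r - patch_radius, r + patch_radius + 1
            c0, c1 = c - patch_radius, c + patch_radius + 1
            sr0, sr1 = r0 - search_radius, r1 + search_radius
            sc0, sc1 = c0 - search_radius, c1 + search_radius
            if r0 < 0 or c0 < 0 or r1 > H or c1 > W or sr0 < 0 or sc0 < 0 or sr1 > H or sc1 > W:
                lost[name] = t
                trk[t] = trk[t - 1]
                continue
            template = prev[r0:r1, c0:c1]
            windows = sliding_window_view(cur[sr0:sr1, sc0:sc1], (side, side))
            ssd = ((windows - template) ** 2).sum(axis=(2, 3)).ravel()
            # ties: smallest displacement wins, then row-major order
            best = np.lexsort((disp_norm, ssd))[0]
            trk[t] = (r + dr.ravel()[best], c + dc.ravel()[best])
    return TrackResult(tracks=tracks, lost=lost)


# ---------------------------------------------------------------------------
# signal extraction & cleaning

@dataclass
class ROISignal:
    name: str
    values: np.ndarray
    flags: np.ndarray  # True where the sample was degraded/replaced

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ROISignalSet:
    signals: dict[str, ROISignal]
    fs: float
    timestamps: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.timestamps}
        for name, sig in self.signals.items():
            data[name] = sig.values
            data[f"{name} flag"] = sig.flags.astype(int)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float) -> "ROISignalSet":
        signals = {}
        for name in ROI_NAMES:
            flags = df.get(f"{name} flag")
            signals[name] = ROISignal(
                name=name,
                values=df[name].to_numpy(dtype=float),
                flags=(flags.to_numpy(dtype=bool) if flags is not None
                       else np.zeros(len(df), dtype=bool)),
            )
        return cls(signals=signals, fs=fs, timestamps=df["time_s"].to_numpy(dtype=float))


def extract_roi_signals(
    stack: ThermalFrameStack,
    rois: list[ROISpec],
    tracks: TrackResult,
    t_low: float = T_LOW_DEFAULT,
    t_high: float = T_HIGH_DEFAULT,
) -> ROISignalSet:
    """Per-frame median temperature of each ROI, mask re-centred on its track.

    A sample is flagged when the ROI falls (partly) outside the image or
    entirely outside the per-frame thresholded face band; flagged samples
    with no usable pixels carry the previous value.
    """
    T, H, W = stack.frames.shape
    signals: dict[str, ROISignal] = {}
    for roi in rois:
        trk = tracks.tracks[roi.name]
        if len(trk) != T:
            raise InsufficientDataError(f"track for {roi.name} does not cover all frames")
        offsets = roi.offsets
        values = np.empty(T)
        flags = np.zeros(T, dtype=bool)
        for t in range(T):
            pix = offsets + trk[t]
            ok = (pix[:, 0] >= 0) & (pix[:, 0] < H) & (pix[:, 1] >= 0) & (pix[:, 1] < W)
            if not ok.all():
                flags[t] = True
            pix = pix[ok]
            if len(pix) == 0:
                values[t] = values[t - 1] if t > 0 else np.nan
                continue
            temps = stack.frames[t][pix[:, 0], pix[:, 1]]
            in_band = (temps > t_low) & (temps < t_high)
            if not in_band.any():
                flags[t] = True
            values[t] = float(np.median(temps))
        signals[roi.name] = ROISignal(name=roi.name, values=values, flags=flags)
    return ROISignalSet(signals=signals, fs=stack.fs, timestamps=stack.timestamps)


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    # centred, edge-truncated (shorter windows at the boundaries)
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def clean_signal(
    signal: ROISignal | np.ndarray,
    window: int = 5,
    sd_threshold: float = 3.0,
) -> ROISignal:
    """Moving-median smoothing followed by 3-SD outlier replacement.

    The moving median (odd window, edge-truncated) is iterated to a fixed
    point so cleaning is idempotent; outlier statistics (mean, SD) are then
    computed once on the whole smoothed signal, and every sample deviating
    by more than ``sd_threshold`` SDs is replaced by the nearest-in-time
    non-outlier value.
    """
    if window % 2 == 0:
        raise ValueError("moving-median window must be odd")
    if isinstance(signal, ROISignal):
        name, values, flags = signal.name, signal.values, signal.flags.copy()
    else:
        values = np.asarray(signal, dtype=float)
        name, flags = "signal", np.zeros(len(values), dtype=bool)
    if len(values) < window:
        raise InsufficientDataError("signal shorter than the filter window")

    x = values.astype(float)
    for _ in range(len(x)):  # repeated median smoothing reaches a root signal
        nx = _moving_median(x, window)
        if np.array_equal(nx, x):
            break
        x = nx

    mu, sd = x.mean(), x.std(ddof=1)
    outlier = np.abs(x - mu) > sd_threshold * sd if sd > 0 else np.zeros(len(x), bool)
    if outlier.all():
        raise UnrecoverableSignalError("every sample is an outlier")
    if outlier.any():
        valid_idx = np.flatnonzero(~outlier)
        for i in np.flatnonzero(outlier):
            j = valid_idx[np.argmin(np.abs(valid_idx - i))]
            x[i] = x[j]
        flags = flags | outlier
    return ROISignal(name=name, values=x, flags=flags)
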