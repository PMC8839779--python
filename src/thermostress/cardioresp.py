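"""Cardiorespiratory processing: RR correction, HRV series and features,
and respiratory frequency.

The interbeat (RR) series is cleaned by flagging beats that deviate from a
local median and replacing them by cubic-spline interpolation, then
resampled to a uniform 4 Hz heart-rate-variability series.  Ten HRV
features are computed across the time (mean/std HRV, RMSSD, pNN50),
frequency (LF%, HF%, LF/HF on a Welch spectrum) and nonlinear (Poincare
SD1/SD2, sample entropy) domains, plus the dominant respiratory frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import (
    CoverageGapError,
    InsufficientDataError,
    NoSpectralPeakError,
    UnusableSeriesError,
)

HRV_FS = 4.0  # Hz, uniform tachogram sampling rate
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class RRSeries:
    """Interbeat intervals (ms) with the beat times (s) that end them."""

    rr_ms: np.ndarray
    beat_times_s: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.rr_ms), dtype=bool)
        if len(self.rr_ms) != len(self.beat_times_s):
            raise ValueError("rr_ms and beat_times_s must have equal length")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @classmethod
    def from_rpeaks(cls, rpeak_times_s: np.ndarray) -> "RRSeries":
        t = np.asarray(rpeak_times_s, dtype=float)
        if len(t) < 2:
            raise InsufficientDataError("need at least 2 R peaks")
        return cls(rr_ms=np.diff(t) * 1000.0, beat_times_s=t[1:])

    def __len__(self) -> int:
        return len(self.rr_ms)


@dataclass
class HRVSeries:
    """Uniformly resampled tachogram, in RR (ms) or heart-rate (bpm) units."""

    values: np.ndarray
    fs: float
    unit: str  # "rr" (ms) | "hr" (bpm)

    def __post_init__(self) -> None:
        if self.unit not in ("rr", "hr"):
            raise ValueError("unit must be 'rr' or 'hr'")


def correct_rr(
    rr: RRSeries,
    local_window: int = 11,
    rel_threshold: float = 0.3,
) -> RRSeries:
    """Replace artifact beats by cubic-spline interpolation over valid beats.

    A beat is flagged when its interval deviates from the local median (11
    beats, edge-truncated) by more than ``rel_threshold`` x that median.
    Beat count and times are preserved; an error is raised when more than
    half the series is flagged.
    """
    if len(rr) < 4:
        raise InsufficientDataError("need at least 4 beats for RR correction")
    med = (
        pd.Series(rr.rr_ms)
        .rolling(local_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    flagged = np.abs(rr.rr_ms - med) > rel_threshold * med
    if flagged.mean() > 0.5:
        raise UnusableSeriesError(
            f"{flagged.sum()}/{len(rr)} beats flagged as artifacts"
        )
    corrected = rr.rr_ms.copy()
    if flagged.any():
        spline = CubicSpline(rr.beat_times_s[~flagged], rr.rr_ms[~flagged])
        corrected[flagged] = spline(rr.beat_times_s[flagged])
    return RRSeries(rr_ms=corrected, beat_times_s=rr.beat_times_s.copy(), flags=flagged)


def rr_to_hrv_series(
    rr: RRSeries,
    duration_s: float,
    unit: str = "hr",
    fs: float = HRV_FS,
    max_gap_s: float = 3.0,
) -> HRVSeries:
    """Cubic-spline tachogram interpolation sampled at exactly ``fs`` Hz.

    ``unit='hr'`` converts beat values to instantaneous heart rate
    (60000/RR, bpm) before interpolation; ``unit='rr'`` keeps milliseconds.
    """
    gaps = np.diff(rr.beat_times_s)
    if len(gaps) and gaps.max() > max_gap_s:
        raise CoverageGapError(f"beat gap of {gaps.max():.2f} s exceeds {max_gap_s} s")
    vals = 60000.0 / rr.rr_ms if unit == "hr" else rr.rr_ms
    spline = CubicSpline(rr.beat_times_s, vals)
    t = np.arange(int(round(duration_s * fs))) / fs
    return HRVSeries(values=spline(t), fs=fs, unit=unit)


# ---------------------------------------------------------------------------
# time-domain features

def hrv_time_features(rr: RRSeries, hrv: HRVSeries) -> dict[str, float]:
    """mean HRV, std HRV (4 Hz series units), RMSSD (ms), pNN50 (%)."""
    if len(rr) < 3:
        raise InsufficientDataError("need at least 3 beats")
    d = np.diff(rr.rr_ms)
    return {
        "mean HRV": float(hrv.values.mean()),
        "std HRV": float(hrv.values.std(ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "pNN50": float(100.0 * np.mean(np.abs(d) > 50.0)) if len(d) else 0.0,
    }


# ---------------------------------------------------------------------------
# frequency-domain features

def hrv_freq_features(
    hrv: HRVSeries,
    welch_window_s: float = 64.0,
) -> dict[str, float]:
    """LF and HF power as % of total (0.04-0.40 Hz) power, and their ratio.

    Welch spectrum with 64 s linearly detrended segments, 50% overlap.
    Band membership is half-open ([low, high)), so the 0.15 Hz boundary
    belongs to HF; the total-power denominator excludes the VLF band.
    """
    n = len(hrv.values)
    if n < 120 * hrv.fs:
        raise InsufficientDataError("need at least 120 s of HRV series")
    nperseg = min(n, int(round(welch_window_s * hrv.fs)))
    f, psd = sps.welch(
        hrv.values, fs=hrv.fs, nperseg=nperseg, noverlap=nperseg // 2, detrend="linear"
    )
    df = f[1] - f[0]
    lf = psd[(f >= LF_BAND[0]) & (f < LF_BAND[1])].sum() * df
    hf = psd[(f >= HF_BAND[0]) & (f < HF_BAND[1])].sum() * df
    total = lf + hf
    if total <= 0:
        return {"LF": 0.0, "HF": 0.0, "LF/HF": 0.0}
    return {
        "LF": float(100.0 * lf / total),
        "HF": float(100.0 * hf / total),
        "LF/HF": float(lf / hf) if hf > 0 else float("inf"),
    }


# ---------------------------------------------------------------------------
# nonlinear features

def poincare_sd(rr_ms: np.ndarray) -> tuple[float, float]:
    """Poincare-plot ellipse axes: SD1 (short-term), SD2 (long-term), ms.

    Population-SD convention, which preserves the identity
    SD1 = RMSSD / sqrt(2) exactly.
    """
    rr_ms = np.asarray(rr_ms, float)
    if len(rr_ms) < 10:
        raise InsufficientDataError("need at least 10 beats for SD1/SD2")
    sd1 = float(np.std(np.diff(rr_ms), ddof=0) / np.sqrt(2.0))
    var2 = 2.0 * np.var(rr_ms, ddof=0) - sd1**2
    return sd1, float(np.sqrt(max(var2, 0.0)))


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None
) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev distance, self-matches excluded.

    A and B count template pairs (i < j, both drawn from the first n-m
    template positions) matching within tolerance r at lengths m+1 and m.
    ``r`` defaults to 0.2 x the population SD, making the statistic invariant
    to affine rescaling.  Degenerate cases (constant series, or no matches)
    return 0 by convention.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < m + 2:
        raise InsufficientDataError("series too short for sample entropy")
    sd = x.std(ddof=0)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def count_matches(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        # pairwise Chebyshev distances, upper triangle only
        total = 0
        for i in range(len(templ) - 1):
            d = np.abs(templ[i + 1 :] - templ[i]).max(axis=1)
            total += int((d <= r).sum())
        return total

    B = count_matches(m)
    A = count_matches(m + 1)
    if A == 0 or B == 0:
        return 0.0
    return float(-np.log(A / B))


def hrv_nonlinear_features(rr: RRSeries) -> dict[str, float]:
    """SD1, SD2 (ms) and sample entropy (m=2, r=0.2 SD) of the RR series."""
    sd1, sd2 = poincare_sd(rr.rr_ms)
    if len(rr) >= 50:
        sampen = sample_entropy(rr.rr_ms)
    else:
        raise InsufficientDataError("need at least 50 beats for sample entropy")
    return {"SD1": sd1, "SD2": sd2, "SampEn": sampen}


# ---------------------------------------------------------------------------
# respiration

def resp_frequency(
    resp: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.05, 1.0),
    welch_window_s: float = 60.0,
    peak_to_floor: float = 5.0,
) -> float:
    """Dominant spectral frequency of the respiration signal in ``band`` (Hz).

    Welch spectrum with linear detrending; the in-band peak must exceed
    ``peak_to_floor`` x the median in-band power (the noise floor).
    """
    resp = np.asarray(resp, float)
    if len(resp) < 60 * fs:
        raise InsufficientDataError("need at least 60 s of respiration signal")
    nperseg = min(len(resp), int(round(welch_window_s * fs)))
    f, psd = sps.welch(resp, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, detrend="linear")
    mask = (f >= band[0]) & (f <= band[1])
    fb, pb = f[mask], psd[mask]
    floor = np.median(pb)
    peak = pb.argmax()
    if floor > 0 and pb[peak] < peak_to_floor * floor:
        raise NoSpectralPeakError("no respiratory peak above the noise floor")
    return float(fb[peak])


def cardioresp_feature_row(
    rpeak_times_s: np.ndarray,
    resp: np.ndarray,
    fs_resp: float,
    duration_s: float,
    hrv_unit: str = "hr",
) -> dict[str, float]:
    """The 10 HRV features plus RESP freq for one session."""
    rr = correct_rr(RRSeries.from_rpeaks(rpeak_times_s))
    hrv = rr_to_hrv_series(rr, duration_s, unit=hrv_unit)
    row = hrv_time_features(rr, hrv)
    row.update(hrv_freq_features(hrv))
    row.update(hrv_nonlinear_features(rr))
    row["RESP freq"] = resp_frequency(resp, fs_resp)
    return row
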