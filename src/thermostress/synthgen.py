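"""Seeded synthetic cohort generator.

The study conditions this generator emulates: two 3-minute sessions per
subject (quiet rest, then a paced Stroop colour-word task), facial thermal
video at 5 Hz, and peripheral autonomic recordings (skin conductance,
R-peak event times, respiration) at 500 Hz.  Under stress the preset
reproduces the directional pattern reported for this protocol: nose tip,
nasal septum and periorbital cooling (Mean and DMean down), left-cheek
warming, raised temperature variability over forehead/cheeks/periorbital/
maxillary areas, a tonic skin-conductance rise with denser phasic
responses, shortened RR intervals with an LF-dominant modulation balance,
and a faster respiratory rhythm.  Magnitudes are free parameters of the
preset: the source protocol reports directions and significance only.

All randomness derives from one root seed through ``numpy.random.SeedSequence``
spawning: one child per subject, one grandchild per session, and one
great-grandchild per signal family (ROI trajectories, motion/pixel noise,
EDA, RR, respiration).  Equal seeds therefore give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidConfigError
from .rois import ROI_LAYOUT, ROI_LABELS, ROI_NAMES

SESSIONS = ("Rest", "Stroop")
#: Class coding used throughout: 1 = Stroop (stress), 2 = Rest.
SESSION_LABELS = {"Stroop": 1, "Rest": 2}


def _default_mean_shift() -> dict[str, float]:
    shifts = {name: 0.0 for name in ROI_NAMES}
    for roi in ("Nose", "N-Sept", "R-POrb", "L-POrb"):
        shifts[roi] = -0.3
    shifts["L-Cheek"] = +0.2
    return shifts


def _default_std_mult() -> dict[str, float]:
    mults = {name: 1.0 for name in ROI_NAMES}
    for roi in (
        "Forehead",
        "R-Forehead",
        "L-Forehead",
        "R-Cheek",
        "L-Cheek",
        "R-POrb",
        "L-POrb",
        "R-Max",
        "L-Max",
    ):
        mults[roi] = 1.5
    return mults


@dataclass
class EffectSizes:
    """Stress-vs-rest effect magnitudes planted by the generator.

    Defaults are the standard stress-effect preset; :meth:`null` gives the zero-effect
    configuration used for calibration runs.
    """

    roi_mean_shift: dict[str, float] = field(default_factory=_default_mean_shift)
    roi_std_mult: dict[str, float] = field(default_factory=_default_std_mult)
    tonic_rest_us: float = 2.0
    tonic_shift_us: float = 1.0
    scr_rate_rest: float = 2.0   # events/min
    scr_rate_stress: float = 8.0
    mean_rr_rest_ms: float = 850.0
    mean_rr_stress_ms: float = 750.0
    lf_amp_rest_ms: float = 25.0
    lf_amp_stress_ms: float = 40.0
    hf_amp_rest_ms: float = 40.0
    hf_amp_stress_ms: float = 15.0
    resp_freq_rest_hz: float = 0.25
    resp_freq_stress_hz: float = 0.35

    def __post_init__(self) -> None:
        for roi in ROI_NAMES:
            self.roi_mean_shift.setdefault(roi, 0.0)
            self.roi_std_mult.setdefault(roi, 1.0)
        if any(m <= 0 for m in self.roi_std_mult.values()):
            raise InvalidConfigError("ROI variability multipliers must be > 0")
        if self.scr_rate_rest < 0 or self.scr_rate_stress < 0:
            raise InvalidConfigError("SCR rates must be >= 0")
        for f in (self.resp_freq_rest_hz, self.resp_freq_stress_hz):
            if not 0.05 < f < 1.0:
                raise InvalidConfigError(f"resp frequency {f} outside (0.05, 1) Hz")

    @classmethod
    def null(cls) -> "EffectSizes":
        """All effects zero: Rest and Stroop sessions are exchangeable."""
        return cls(
            roi_mean_shift={n: 0.0 for n in ROI_NAMES},
            roi_std_mult={n: 1.0 for n in ROI_NAMES},
            tonic_shift_us=0.0,
            scr_rate_stress=2.0,
            mean_rr_stress_ms=850.0,
            lf_amp_stress_ms=25.0,
            hf_amp_stress_ms=40.0,
            resp_freq_stress_hz=0.25,
        )

    @property
    def informative_features(self) -> set[str]:
        """Feature names carrying a nonzero planted effect."""
        out: set[str] = set()
        for roi, shift in self.roi_mean_shift.items():
            if shift != 0.0:
                out.add(f"{ROI_LABELS[roi]} Mean")
                out.add(f"{ROI_LABELS[roi]} DMean")
        for roi, mult in self.roi_std_mult.items():
            if mult != 1.0:
                out.add(f"{ROI_LABELS[roi]} Std")
        if self.tonic_shift_us != 0.0:
            out.add("TonicMean")
        if self.scr_rate_stress != self.scr_rate_rest:
            out.update({"NPks", "PksSum", "PksMax", "PhasicMean", "PhasicStd"})
        if self.mean_rr_stress_ms != self.mean_rr_rest_ms:
            out.add("mean HRV")
        if (
            self.lf_amp_stress_ms != self.lf_amp_rest_ms
            or self.hf_amp_stress_ms != self.hf_amp_rest_ms
        ):
            out.update({"LF", "HF", "LF/HF"})
        if self.hf_amp_stress_ms != self.hf_amp_rest_ms:
            # HF modulation drives beat-to-beat variability measures
            out.update({"RMSSD", "pNN50", "SD1", "SD2", "std HRV"})
        if self.resp_freq_stress_hz != self.resp_freq_rest_hz:
            out.add("RESP freq")
        return out


@dataclass
class CohortConfig:
    """Study-condition constants and nuisance magnitudes for one cohort."""

    n_subjects: int = 19
    session_duration_s: float = 180.0
    fs_thermal: float = 5.0
    fs_physio: float = 500.0
    frame_size: tuple[int, int] = (64, 64)
    effect: EffectSizes = field(default_factory=EffectSizes)
    seed: int = 0
    render_thermal: bool = True
    thermal_noise_sd: float = 0.05  # degC per pixel
    roi_wander_sd: float = 0.10     # degC, rest-session trajectory SD
    motion_step_prob: float = 0.15  # per-axis probability of a +/-1 px step
    motion_max_px: int = 3
    eda_noise_sd: float = 0.01      # uS
    rr_noise_sd_ms: float = 5.0
    resp_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidConfigError("n_subjects must be >= 2")
        if self.session_duration_s <= 0:
            raise InvalidConfigError("session_duration_s must be > 0")
        if self.fs_thermal <= 0 or self.fs_physio <= 0:
            raise InvalidConfigError("sampling rates must be > 0")


@dataclass
class SessionTruth:
    """Ground truth planted in one session."""

    roi_trajectories: dict[str, np.ndarray]  # degC, length T
    scr_times: np.ndarray                    # s
    rpeak_times: np.ndarray                  # s
    resp_freq: float                         # Hz
    motion: np.ndarray                       # (T, 2) int px, applied face translation
    face_origin: np.ndarray                  # (T, 2) int px, face-box top-left
    face_size: tuple[int, int]
    landmarks: list[dict[str, tuple[float, float]]]


@dataclass
class SessionRecord:
    subject: str
    session: str  # "Rest" | "Stroop"
    label: int    # 1 = Stroop, 2 = Rest
    thermal: "object"  # ThermalFrameStack | None (import cycle avoided)
    eda: np.ndarray
    rpeak_times: np.ndarray
    resp: np.ndarray
    fs_physio: float


@dataclass
class Cohort:
    config: CohortConfig
    sessions: list[SessionRecord]

    def subjects(self) -> list[str]:
        seen: list[str] = []
        for rec in self.sessions:
            if rec.subject not in seen:
                seen.append(rec.subject)
        return seen


GroundTruth = dict  # (subject, session) -> SessionTruth


# ---------------------------------------------------------------------------
# face geometry helpers

def face_geometry(frame_size: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int], int]:
    """Face-box origin, size and painted ROI patch side for a frame size.

    The face occupies the central 60% of the frame, leaving a margin wide
    enough for the block-matching tracker's template-plus-search window even
    at the maximum simulated head translation.
    """
    H, W = frame_size
    fh, fw = round(0.60 * H), round(0.60 * W)
    origin = (round(0.20 * H), round(0.20 * W))
    patch = round(0.17 * fh)
    patch += 1 - patch % 2  # odd
    return origin, (fh, fw), max(patch, 3)


def roi_centres(face_origin: tuple[int, int], face_size: tuple[int, int]) -> dict[str, tuple[int, int]]:
    r0, c0 = face_origin
    fh, fw = face_size
    return {
        name: (r0 + round(fr * (fh - 1)), c0 + round(fc * (fw - 1)))
        for name, (fr, fc) in ROI_LAYOUT.items()
    }


def _contour(origin: tuple[int, int], size: tuple[int, int]) -> np.ndarray:
    r0, c0 = origin
    fh, fw = size
    return np.array(
        [[r0, c0], [r0, c0 + fw - 1], [r0 + fh - 1, c0 + fw - 1], [r0 + fh - 1, c0]],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# signal generators

def generate_thermal_frames(
    roi_truth: dict[str, np.ndarray],
    motion: np.ndarray,
    noise_sd: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    base_face_temp: float = 35.5,
    background_temp: float = 25.0,
):
    """Render a thermal frame stack from planted ROI trajectories.

    The face is a warm rectangle (within the 30-38 degC face band) on a cool
    background; each of the 14 ROI patches is painted with its true
    trajectory value plus i.i.d. pixel noise.  ``motion`` is a per-frame
    integer (row, col) translation of the whole face; landmark metadata
    follows it exactly.
    """
    from .thermal import ThermalFrameStack  # local import: no module cycle

    rng = np.random.default_rng() if rng is None else rng
    H, W = config.frame_size
    origin0, (fh, fw), patch = face_geometry(config.frame_size)
    lengths = {len(v) for v in roi_truth.values()}
    n_frames = int(round(config.session_duration_s * config.fs_thermal))
    if lengths != {n_frames}:
        raise InvalidConfigError(
            f"ROI trajectories must all have length {n_frames}, got {sorted(lengths)}"
        )
    motion = np.asarray(motion, dtype=int)
    if motion.shape != (n_frames, 2):
        raise InvalidConfigError("motion must be (n_frames, 2)")

    half = patch // 2
    frames = np.empty((n_frames, H, W), dtype=np.float64)
    landmarks: list[dict[str, tuple[float, float]]] = []
    contours: list[np.ndarray] = []
    face_origin = np.empty((n_frames, 2), dtype=int)
    for t in range(n_frames):
        r0 = origin0[0] + motion[t, 0]
        c0 = origin0[1] + motion[t, 1]
        if r0 < 0 or c0 < 0 or r0 + fh > H or c0 + fw > W:
            raise InvalidConfigError(f"motion pushes face outside frame at frame {t}")
        face_origin[t] = (r0, c0)
        frame = np.full((H, W), background_temp, dtype=np.float64)
        if noise_sd > 0:
            frame += rng.normal(0.0, noise_sd, size=(H, W))
        face = np.full((fh, fw), base_face_temp)
        if noise_sd > 0:
            face += rng.normal(0.0, noise_sd, size=(fh, fw))
        centres = roi_centres((r0, c0), (fh, fw))
        for name in ROI_NAMES:
            cr, cc = centres[name]
            rr, cc_ = cr - r0, cc - c0
            vals = np.full((patch, patch), roi_truth[name][t])
            if noise_sd > 0:
                vals += rng.normal(0.0, noise_sd, size=(patch, patch))
            face[rr - half : rr + half + 1, cc_ - half : cc_ + half + 1] = vals
        frame[r0 : r0 + fh, c0 : c0 + fw] = face
        frames[t] = frame
        landmarks.append({n: (float(p[0]), float(p[1])) for n, p in centres.items()})
        contours.append(_contour((r0, c0), (fh, fw)))

    timestamps = np.arange(n_frames) / config.fs_thermal
    return ThermalFrameStack(
        frames=frames,
        fs=config.fs_thermal,
        timestamps=timestamps,
        landmarks=landmarks,
        contours=contours,
    ), face_origin


def scr_kernel(fs: float, tau_rise: float = 0.7, tau_decay: float = 2.0) -> np.ndarray:
    """Biexponential (Bateman) response, unit peak amplitude."""
    t = np.arange(0.0, 8.0 * tau_decay, 1.0 / fs)
    h = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return h / h.max()


def generate_eda_signal(
    tonic_level: float,
    scr_rate: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.01,
    tau_rise: float = 0.7,
    tau_decay: float = 2.0,
    tonic_wander_amp: float = 0.1,
    amp_mean_us: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Skin conductance = slow tonic + sparse biexponential SCRs + noise.

    SCR onsets follow a homogeneous Poisson process at ``scr_rate`` events
    per minute; amplitudes are log-normal around ``amp_mean_us``.  The tonic
    is band-limited below 0.05 Hz (a sum of slow sinusoids), so the
    decomposition's tonic/phasic split is well defined.  Returns the signal
    (uS) and the true event onset times (s).
    """
    if scr_rate < 0:
        raise InvalidConfigError("scr_rate must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    tonic = np.full(n, float(tonic_level))
    for k in range(1, 4):
        f = rng.uniform(0.003, 0.045)
        phase = rng.uniform(0, 2 * np.pi)
        tonic += (tonic_wander_amp / k) * np.sin(2 * np.pi * f * t + phase)

    events: list[float] = []
    if scr_rate > 0:
        t_ev = rng.exponential(60.0 / scr_rate)
        while t_ev < duration_s:
            events.append(t_ev)
            t_ev += rng.exponential(60.0 / scr_rate)
    driver = np.zeros(n)
    amps = np.exp(rng.normal(np.log(amp_mean_us), 0.4, size=len(events)))
    for t_ev, a in zip(events, amps):
        driver[int(round(t_ev * fs))] += a
    phasic = np.convolve(driver, scr_kernel(fs, tau_rise, tau_decay))[:n]

    signal = tonic + phasic
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return signal, np.asarray(events)


def generate_rr_and_resp(
    mean_rr: float,
    lf_amp: float,
    hf_amp: float,
    resp_freq: float,
    duration_s: float,
    rng: np.random.Generator | None = None,
    rr_noise_sd: float = 5.0,
    resp_fs: float = 500.0,
    resp_noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """R-peak times with LF (0.1 Hz) and respiration-locked HF modulation.

    RR_k = mean_rr + lf_amp sin(2 pi 0.1 t_k) + hf_amp sin(2 pi f_resp t_k)
    + Gaussian noise; the respiration channel is a sinusoid at ``resp_freq``.
    Returns (rpeak_times_s, rr_ms, resp_signal).
    """
    if not 300.0 < mean_rr < 1500.0:
        raise InvalidConfigError(f"mean_rr {mean_rr} outside (300, 1500) ms")
    if mean_rr - abs(lf_amp) - abs(hf_amp) <= 0:
        raise InvalidConfigError("modulation amplitudes would drive RR <= 0")
    rng = np.random.default_rng() if rng is None else rng

    times = [0.0]
    rrs: list[float] = []
    t = 0.0
    while True:
        rr = (
            mean_rr
            + lf_amp * np.sin(2 * np.pi * 0.1 * t)
            + hf_amp * np.sin(2 * np.pi * resp_freq * t)
        )
        if rr_noise_sd > 0:
            rr += rng.normal(0.0, rr_noise_sd)
        if t + rr / 1000.0 > duration_s:
            break
        t += rr / 1000.0
        times.append(t)
        rrs.append(rr)

    n = int(round(duration_s * resp_fs))
    tt = np.arange(n) / resp_fs
    resp = np.sin(2 * np.pi * resp_freq * tt)
    if resp_noise_sd > 0:
        resp = resp + rng.normal(0.0, resp_noise_sd, size=n)
    return np.asarray(times), np.asarray(rrs), resp


# ---------------------------------------------------------------------------
# cohort assembly

def _session_motion(rng: np.random.Generator, n_frames: int, config: CohortConfig) -> np.ndarray:
    steps = rng.choice(
        [-1, 0, 1],
        size=(n_frames, 2),
        p=[config.motion_step_prob / 2, 1 - config.motion_step_prob, config.motion_step_prob / 2],
    )
    steps[0] = 0
    motion = np.cumsum(steps, axis=0)
    return np.clip(motion, -config.motion_max_px, config.motion_max_px)


def _session_roi_truth(
    rng: np.random.Generator,
    base_temps: dict[str, float],
    stress: bool,
    config: CohortConfig,
) -> dict[str, np.ndarray]:
    eff = config.effect
    n_t = int(round(config.session_duration_s * config.fs_thermal))
    smooth_sigma = 2.0 * config.fs_thermal  # ~2 s correlation length
    truth = {}
    for name in ROI_NAMES:
        w = gaussian_filter1d(rng.standard_normal(n_t), smooth_sigma, mode="reflect")
        w = (w - w.mean()) / max(w.std(), 1e-12)
        amp = config.roi_wander_sd * (eff.roi_std_mult[name] if stress else 1.0)
        traj = base_temps[name] + amp * w
        shift = eff.roi_mean_shift[name] if stress else 0.0
        if shift != 0.0:
            half_range = np.sign(shift) * min(0.15, abs(shift))
            traj = traj + np.linspace(shift - half_range, shift + half_range, n_t)
        truth[name] = traj
    return truth


def generate_session(
    subject: str,
    session: str,
    seedseq: np.random.SeedSequence,
    base_temps: dict[str, float],
    config: CohortConfig,
) -> tuple[SessionRecord, SessionTruth]:
    """Generate one session record plus its ground truth."""
    eff = config.effect
    stress = session == "Stroop"
    ss_roi, ss_frames, ss_eda, ss_rr, ss_resp = seedseq.spawn(5)

    roi_truth = _session_roi_truth(np.random.default_rng(ss_roi), base_temps, stress, config)

    n_frames = int(round(config.session_duration_s * config.fs_thermal))
    rng_frames = np.random.default_rng(ss_frames)
    motion = _session_motion(rng_frames, n_frames, config)
    stack = None
    origin0, face_size, _ = face_geometry(config.frame_size)
    face_origin = np.asarray(origin0) + motion
    landmarks: list[dict[str, tuple[float, float]]] = []
    if config.render_thermal:
        stack, face_origin = generate_thermal_frames(
            roi_truth, motion, config.thermal_noise_sd, config, rng=rng_frames
        )
        landmarks = stack.landmarks

    tonic = eff.tonic_rest_us + (eff.tonic_shift_us if stress else 0.0)
    rate = eff.scr_rate_stress if stress else eff.scr_rate_rest
    eda, scr_times = generate_eda_signal(
        tonic,
        rate,
        config.session_duration_s,
        config.fs_physio,
        rng=np.random.default_rng(ss_eda),
        noise_sd=config.eda_noise_sd,
    )

    resp_freq = eff.resp_freq_stress_hz if stress else eff.resp_freq_rest_hz
    rpeaks, _rr, resp = generate_rr_and_resp(
        eff.mean_rr_stress_ms if stress else eff.mean_rr_rest_ms,
        eff.lf_amp_stress_ms if stress else eff.lf_amp_rest_ms,
        eff.hf_amp_stress_ms if stress else eff.hf_amp_rest_ms,
        resp_freq,
        config.session_duration_s,
        rng=np.random.default_rng(ss_rr),
        rr_noise_sd=config.rr_noise_sd_ms,
        resp_fs=config.fs_physio,
        resp_noise_sd=config.resp_noise_sd,
    )
    # independent stream reserved for respiration-specific nuisance (unused
    # for now; spawning it keeps per-signal streams stable across versions)
    _ = ss_resp

    record = SessionRecord(
        subject=subject,
        session=session,
        label=SESSION_LABELS[session],
        thermal=stack,
        eda=eda,
        rpeak_times=rpeaks,
        resp=resp,
        fs_physio=config.fs_physio,
    )
    truth = SessionTruth(
        roi_trajectories=roi_truth,
        scr_times=scr_times,
        rpeak_times=rpeaks,
        resp_freq=resp_freq,
        motion=motion,
        face_origin=face_origin,
        face_size=face_size,
        landmarks=landmarks,
    )
    return record, truth


def iter_sessions(config: CohortConfig):
    """Yield (SessionRecord, SessionTruth) one at a time (bounded memory)."""
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    for i, subj_ss in enumerate(subject_seeds):
        subject = f"S{i + 1:02d}"
        rng_subj = np.random.default_rng(subj_ss)
        base_temps = {name: rng_subj.uniform(32.8, 34.2) for name in ROI_NAMES}
        for session, sess_ss in zip(SESSIONS, subj_ss.spawn(2)):
            yield generate_session(subject, session, sess_ss, base_temps, config)


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate the full cohort: 2 sessions (Rest, Stroop) per subject."""
    records: list[SessionRecord] = []
    truth: GroundTruth = {}
    for record, sess_truth in iter_sessions(config):
        records.append(record)
        truth[(record.subject, record.session)] = sess_truth
    return Cohort(config=config, sessions=records), truth


# ---------------------------------------------------------------------------
# disk output

def write_session(record: SessionRecord, outdir: Path) -> None:
    """Write one session: multi-page float32 TIFF + JSON sidecar + CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if record.thermal is not None:
        stack = record.thermal
        tifffile.imwrite(outdir / "thermal.tiff", stack.frames.astype(np.float32))
        sidecar = {
            "fs": stack.fs,
            "timestamps": stack.timestamps.tolist(),
            "pixel_convention": "0-based (row, col)",
            "landmarks": [
                {name: list(pt) for name, pt in frame_lm.items()}
                for frame_lm in stack.landmarks
            ],
            "contours": [c.tolist() for c in stack.contours],
        }
        (outdir / "thermal.json").write_text(json.dumps(sidecar))
    n = len(record.eda)
    t = np.arange(n) / record.fs_physio
    _write_csv(outdir / "eda.csv", "time_s,microsiemens", np.column_stack([t, record.eda]))
    rr_ms = np.diff(record.rpeak_times) * 1000.0
    _write_csv(
        outdir / "rr.csv",
        "beat_time_s,rr_ms",
        np.column_stack([record.rpeak_times[1:], rr_ms]),
    )
    nr = len(record.resp)
    tr = np.arange(nr) / record.fs_physio
    _write_csv(outdir / "resp.csv", "time_s,value", np.column_stack([tr, record.resp]))


def _write_csv(path: Path, header: str, data: np.ndarray) -> None:
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.9g")


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir: Path) -> None:
    """Write a cohort tree: <out>/<subject>/<session>/ plus labels and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["subject,session,label"]
    for rec in cohort.sessions:
        write_session(rec, outdir / rec.subject / rec.session)
        rows.append(f"{rec.subject},{rec.session},{rec.label}")
    (outdir / "labels.csv").write_text("\n".join(rows) + "\n")
    gt = {
        f"{subj}/{sess}": {
            "scr_times": st.scr_times.tolist(),
            "rpeak_times": st.rpeak_times.tolist(),
            "resp_freq": st.resp_freq,
            "motion": st.motion.tolist(),
            "face_origin": st.face_origin.tolist(),
            "face_size": list(st.face_size),
            "roi_trajectories": {k: v.tolist() for k, v in st.roi_trajectories.items()},
        }
        for (subj, sess), st in truth.items()
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt))
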