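"""Per-frame feature extraction inside the selected 5-min window.

The selected window of each session is divided into non-overlapping
frames of 30 s or 60 s, and each frame is summarized by the selected
feature set:

ECG
    heart rate, mean RR interval, HRV band powers (Lomb-Scargle over the
    Task-Force bands ULF <= 0.003 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz)
    and median T-wave amplitude.  Note that ULF is physically
    under-resolved on 30-60 s frames; its value mostly reflects the
    within-frame RR trend and is computed for fidelity to the selected
    feature set.
EDA
    mean tonic (< 0.05 Hz) level and SCR peak count of the phasic
    residual (>= 0.01 µS rise from the preceding onset).
EMG (per muscle)
    mean rectified-and-smoothed envelope and pulse-onset count
    (envelope crossings of a session-calibrated robust threshold held
    for >= 100 ms).

R-peak detection is a Pan-Tompkins-style derivative-square-integrate
detector with a scale-free adaptive threshold and a 200-ms refractory
period; frames with fewer than 5 detected beats are dropped (with a
logged reason) rather than yielding NaN features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .syncwin import WindowSelection
from .synthio import RecordingSession

__all__ = [
    "FrameSpec",
    "FEATURE_COLUMNS",
    "detect_r_peaks",
    "hrv_features",
    "t_wave_amplitude",
    "eda_features",
    "emg_features",
    "extract_frames",
    "extract_cohort_features",
]

log = logging.getLogger(__name__)

HRV_BANDS = {"ulf": (0.0005, 0.003), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}

FEATURE_COLUMNS = (
    "ecg_heart_rate",
    "ecg_rr_mean",
    "ecg_hrv_hf",
    "ecg_hrv_lf",
    "ecg_hrv_ulf",
    "ecg_t_wave_amp",
    "eda_tonic_mean",
    "eda_scr_peak_count",
    "emg_z_envelope_mean",
    "emg_z_pulse_onset_count",
    "emg_mf_envelope_mean",
    "emg_mf_pulse_onset_count",
)


@dataclass(frozen=True)
class FrameSpec:
    """Non-overlapping framing of the 300-s window."""

    frame_s: int = 30

    def __post_init__(self) -> None:
        if self.frame_s not in (30, 60):
            raise ValueError("frame_s must be 30 or 60")

    def n_frames(self, window_s: int = 300) -> int:
        if window_s % self.frame_s:
            raise ValueError("window length not divisible by frame length")
        return window_s // self.frame_s


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (s) in a filtered ECG segment.

    Derivative -> squaring -> 150-ms moving-window integration, peaks
    above an adaptive (percentile-based, hence amplitude-scale-invariant)
    threshold with a 200-ms refractory period, each refined to the local
    signal maximum within +-50 ms.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < fs:
        return np.empty(0)
    deriv = np.gradient(x)
    sq = deriv ** 2
    win = max(int(round(0.15 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    top = np.percentile(integ, 99.0)
    if top <= 0:
        return np.empty(0)
    peaks, _ = signal.find_peaks(integ, height=0.3 * top,
                                 distance=int(round(0.2 * fs)))
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    return refined / fs


def hrv_features(r_peak_times: np.ndarray, frame_start_s: float,
                 frame_len_s: float) -> dict[str, float] | None:
    """Heart rate, mean RR and Lomb-Scargle HRV band powers for one frame.

    Returns ``None`` (invalid frame) with fewer than 4 RR intervals.
    Band powers integrate the Lomb-Scargle periodogram of the centered
    RR tachogram (RR value timestamped at the later beat) over each band.
    """
    t = np.asarray(r_peak_times, dtype=float)
    t = t[(t >= frame_start_s) & (t < frame_start_s + frame_len_s)]
    if t.size < 5:
        return None
    rr = np.diff(t)
    rr_mean = float(np.mean(rr))
    out = {"ecg_rr_mean": rr_mean, "ecg_heart_rate": 60.0 / rr_mean}
    tach_t, tach_y = t[1:], rr - rr.mean()
    for name, (f_lo, f_hi) in HRV_BANDS.items():
        freqs = np.linspace(f_lo, f_hi, 40)
        pgram = signal.lombscargle(tach_t, tach_y, 2 * np.pi * freqs,
                                   normalize=False)
        df = freqs[1] - freqs[0]
        out[f"ecg_hrv_{name}"] = float(np.sum(pgram) * df)
    return out


def t_wave_amplitude(ecg: np.ndarray, r_peak_times: np.ndarray,
                     fs: float) -> float | None:
    """Median T-wave amplitude (mV) over the beats of a segment.

    Per beat, T is the maximum deflection 120-400 ms after R, measured
    relative to the PR-segment baseline (mean of the 100-60 ms interval
    before R); beats whose T window runs past the signal are skipped.
    """
    x = np.asarray(ecg, dtype=float)
    amps = []
    for rt in np.asarray(r_peak_times, dtype=float):
        i_r = int(round(rt * fs))
        t_lo, t_hi = i_r + int(0.12 * fs), i_r + int(0.40 * fs)
        b_lo, b_hi = i_r - int(0.10 * fs), i_r - int(0.06 * fs)
        if b_lo < 0 or t_hi > x.size:
            continue
        baseline = float(np.mean(x[b_lo:b_hi]))
        amps.append(float(np.max(x[t_lo:t_hi]) - baseline))
    if len(amps) < 2:
        return None
    return float(np.median(amps))


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def _eda_tonic(eda: np.ndarray, fs: float) -> np.ndarray:
    """Tonic (< 0.05 Hz) component.  The signal is decimated to ~10 Hz
    before the Butterworth low-pass for numerical stability at the very
    low normalized cutoff, then linearly re-interpolated."""
    x = np.asarray(eda, dtype=float)
    step = max(int(fs // 10), 1)
    xd = x[::step]
    fsd = fs / step
    if xd.size < 30:
        return np.full_like(x, x.mean())
    sos = signal.butter(2, 0.05, btype="lowpass", fs=fsd, output="sos")
    td = signal.sosfiltfilt(sos, xd)
    idx = np.arange(x.size) / step
    return np.interp(idx, np.arange(xd.size), td)


def eda_features(eda: np.ndarray, fs: float, frame_start_s: float = 0.0,
                 frame_len_s: float | None = None) -> dict[str, float]:
    """Mean tonic level and SCR peak count for one frame of an EDA segment.

    The tonic/phasic split is computed on the whole segment; phasic SCR
    peaks are local maxima rising >= 0.01 µS from their preceding onset
    (prominence from the left base).  Counts use peak times within the
    frame.
    """
    x = np.asarray(eda, dtype=float)
    if frame_len_s is None:
        frame_len_s = x.size / fs
    tonic = _eda_tonic(x, fs)
    phasic = x - tonic
    i0, i1 = int(frame_start_s * fs), int((frame_start_s + frame_len_s) * fs)
    peaks, _ = signal.find_peaks(phasic, prominence=0.01,
                                 distance=int(round(0.5 * fs)))
    n_in_frame = int(np.sum((peaks >= i0) & (peaks < i1)))
    return {
        "eda_tonic_mean": float(np.mean(tonic[i0:i1])),
        "eda_scr_peak_count": float(n_in_frame),
    }


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def emg_envelope(emg: np.ndarray, fs: float) -> np.ndarray:
    """Linear envelope: 10-Hz zero-phase low-pass of the rectified signal."""
    sos = signal.butter(4, 10.0, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.abs(np.asarray(emg, dtype=float)))


def emg_features(emg: np.ndarray, fs: float, frame_start_s: float = 0.0,
                 frame_len_s: float | None = None,
                 threshold: float | None = None) -> dict[str, float]:
    """Mean envelope and pulse-onset count for one frame of an EMG segment.

    Onsets are upward crossings of ``threshold`` (default: envelope
    median + 3 MAD over the whole segment, a burst-robust baseline
    calibration) that stay above it for >= 100 ms.
    """
    x = np.asarray(emg, dtype=float)
    if frame_len_s is None:
        frame_len_s = x.size / fs
    env = emg_envelope(x, fs)
    if threshold is None:
        med = np.median(env)
        mad = np.median(np.abs(env - med))
        threshold = med + 3.0 * mad
    above = env > threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    min_run = int(round(0.10 * fs))
    onsets = []
    for r in rising:
        end = r
        while end < above.size and above[end]:
            end += 1
        if end - r >= min_run:
            onsets.append(r)
    onsets = np.asarray(onsets)
    i0, i1 = int(frame_start_s * fs), int((frame_start_s + frame_len_s) * fs)
    n_in_frame = int(np.sum((onsets >= i0) & (onsets < i1))) if onsets.size else 0
    return {
        "emg_envelope_mean": float(np.mean(env[i0:i1])),
        "emg_pulse_onset_count": float(n_in_frame),
    }


# ---------------------------------------------------------------------------
# framing
# ---------------------------------------------------------------------------

def _cut(x: np.ndarray, start_s: int, length_s: int, fs: float) -> np.ndarray:
    i0 = int(round(start_s * fs))
    i1 = i0 + int(round(length_s * fs))
    if i0 < 0 or i1 > x.size:
        raise ValueError("window falls outside the recorded signal")
    return x[i0:i1]


def extract_frames(session: RecordingSession, window: WindowSelection,
                   frame_spec: FrameSpec) -> pd.DataFrame:
    """Extract the selected feature set per frame of the chosen window.

    ``session`` is expected to be preprocessed (filtered).  The window is
    cut per channel at ``window.channel_start_s`` so per-channel lag
    shifts carry through to the raw signals.  Invalid frames (fewer than
    5 beats) are dropped with a logged reason.
    """
    fs = session.fs
    w = window.length_s
    cuts = {c: _cut(session.channels[c], window.channel_start_s(c), w, fs)
            for c in session.channels}
    r_times = detect_r_peaks(cuts["ecg"], fs)
    # session-level EMG onset thresholds (burst-robust)
    thresholds = {}
    for ch in ("emg_z", "emg_mf"):
        env = emg_envelope(cuts[ch], fs)
        med = np.median(env)
        thresholds[ch] = med + 3.0 * np.median(np.abs(env - med))

    rows = []
    for fi in range(frame_spec.n_frames(w)):
        f0 = fi * frame_spec.frame_s
        hrv = hrv_features(r_times, f0, frame_spec.frame_s)
        if hrv is None:
            log.info("dropping frame %d of %s/%s: <5 beats detected",
                     fi, session.subject_id, session.condition)
            continue
        in_frame = (r_times >= f0) & (r_times < f0 + frame_spec.frame_s)
        t_amp = t_wave_amplitude(cuts["ecg"], r_times[in_frame], fs)
        if t_amp is None:
            log.info("dropping frame %d of %s/%s: too few T waves",
                     fi, session.subject_id, session.condition)
            continue
        row: dict[str, object] = {
            "subject_id": session.subject_id,
            "condition": session.condition,
            "frame_idx": fi,
        }
        row.update(hrv)
        row["ecg_t_wave_amp"] = t_amp
        row.update(eda_features(cuts["eda"], fs, f0, frame_spec.frame_s))
        for ch in ("emg_z", "emg_mf"):
            f = emg_features(cuts[ch], fs, f0, frame_spec.frame_s,
                             threshold=thresholds[ch])
            row[f"{ch}_envelope_mean"] = f["emg_envelope_mean"]
            row[f"{ch}_pulse_onset_count"] = f["emg_pulse_onset_count"]
        rows.append(row)
    cols = ["subject_id", "condition", "frame_idx", *FEATURE_COLUMNS]
    df = pd.DataFrame(rows, columns=cols)
    if df[list(FEATURE_COLUMNS)].isna().any().any():
        raise AssertionError("NaN feature after extraction")
    return df


def extract_cohort_features(sessions_with_windows, frame_spec: FrameSpec
                            ) -> pd.DataFrame:
    """Concatenate :func:`extract_frames` over (session, window) pairs."""
    frames = [extract_frames(s, w, frame_spec) for s, w in sessions_with_windows]
    return pd.concat(frames, ignore_index=True)
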