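"""Per-channel signal-conditioning filters.

ECG: Butterworth low-pass, 40 Hz cutoff.  EMG: linear-phase FIR band-pass,
20-450 Hz.  EDA: Butterworth low-pass, 5 Hz cutoff.  All filters are
length-preserving and applied zero-phase (forward-backward for the IIR
paths, group-delay-compensated convolution on a reflect-padded input for
the FIR path) so that downstream feature timing is not shifted.  Orders
are conventional biosignal defaults (Butterworth order 4, 501 Hamming
taps) and are exposed through :class:`FilterSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import CHANNELS
from .synthio import RecordingSession

__all__ = [
    "FilterSpec",
    "ECG_FILTER",
    "EMG_FILTER",
    "EDA_FILTER",
    "design_filter",
    "filter_ecg",
    "filter_emg",
    "filter_eda",
    "preprocess_session",
]


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one conditioning filter.

    ``kind`` is ``"lowpass_iir"`` (Butterworth, ``order``) or
    ``"bandpass_fir"`` (Hamming-windowed, ``order`` taps).
    """

    kind: str
    cutoffs_hz: tuple[float, ...]
    order: int
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass_iir", "bandpass_fir"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if any(c <= 0 for c in self.cutoffs_hz):
            raise ValueError("cutoffs must be positive")


ECG_FILTER = FilterSpec("lowpass_iir", (40.0,), order=4)
EMG_FILTER = FilterSpec("bandpass_fir", (20.0, 450.0), order=501)
EDA_FILTER = FilterSpec("lowpass_iir", (5.0,), order=4)


def design_filter(spec: FilterSpec, fs: float):
    """Return filter coefficients: SOS array for IIR, taps for FIR."""
    if any(c >= fs / 2 for c in spec.cutoffs_hz):
        raise ValueError("cutoff at or above Nyquist")
    if spec.kind == "lowpass_iir":
        return signal.butter(spec.order, spec.cutoffs_hz[0], btype="lowpass",
                             fs=fs, output="sos")
    return signal.firwin(spec.order, list(spec.cutoffs_hz), pass_zero=False,
                         window="hamming", fs=fs)


def _apply(spec: FilterSpec, x: np.ndarray, fs: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D signal")
    coeffs = design_filter(spec, fs)
    if spec.kind == "lowpass_iir":
        if spec.zero_phase:
            return signal.sosfiltfilt(coeffs, x)
        return signal.sosfilt(coeffs, x)
    # FIR: reflect-pad, convolve, crop at the (taps-1)/2 group delay so the
    # linear-phase filter acts with zero net delay and preserved length.
    taps = coeffs
    half = (len(taps) - 1) // 2
    pad = min(len(taps), x.size - 1)
    xp = np.pad(x, pad, mode="reflect")
    y = signal.fftconvolve(xp, taps, mode="same")
    return y[pad:pad + x.size]


def filter_ecg(x: np.ndarray, fs: float) -> np.ndarray:
    """40-Hz Butterworth low-pass (zero phase) for the ECG channel."""
    if fs <= 80.0:
        raise ValueError("fs must exceed 80 Hz for the 40-Hz ECG filter")
    return _apply(ECG_FILTER, x, fs)


def filter_emg(x: np.ndarray, fs: float) -> np.ndarray:
    """20-450 Hz linear-phase FIR band-pass for EMG channels."""
    if fs <= 900.0:
        raise ValueError("fs must exceed 900 Hz for the 20-450 Hz EMG filter")
    return _apply(EMG_FILTER, x, fs)


def filter_eda(x: np.ndarray, fs: float) -> np.ndarray:
    """5-Hz Butterworth low-pass (zero phase) for the EDA channel."""
    if fs <= 10.0:
        raise ValueError("fs must exceed 10 Hz for the 5-Hz EDA filter")
    return _apply(EDA_FILTER, x, fs)


_CHANNEL_FILTERS = {
    "ecg": filter_ecg,
    "eda": filter_eda,
    "emg_z": filter_emg,
    "emg_mf": filter_emg,
}


def preprocess_session(session: RecordingSession) -> RecordingSession:
    """Return a copy of ``session`` with every channel conditioned."""
    channels = {c: _CHANNEL_FILTERS[c](session.channels[c], session.fs)
                for c in CHANNELS}
    return RecordingSession(
        subject_id=session.subject_id,
        condition=session.condition,
        fs=session.fs,
        channels=channels,
        ground_truth=session.ground_truth,
    )
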