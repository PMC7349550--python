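"""Synthetic multi-channel physiological cohort generation.

Emulates the statistical structure of a film-elicitation emotion study:
each subject contributes one ~30-min session per emotional condition
(neutral, fear, happy), recorded on four channels at 1000 Hz — ECG (mV),
EDA (µS), zygomaticus EMG and medial-frontalis EMG (mV).  Conditions
modulate mean heart rate, LF/HF RR-interval variability, T-wave amplitude
and its beat-to-beat spread, SCR event rate, tonic skin-conductance level
and muscle-specific EMG burst rates (zygomaticus under happiness,
medial frontalis under fear).  A high-activation "hotspot" interval of
fixed length multiplies local event rates and RR variability so that the
compression-based information profile peaks there; its onset may be
offset per channel by an integer number of seconds to exercise the lag
synchronization stage.  Every session carries full ground truth (R-peak
times, SCR event times, EMG burst intervals, per-channel hotspot
interval, drawn parameters), which enables recovery tests.

Amplitudes are in mV (ECG, EMG) and µS (EDA); times in seconds from
session start.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from . import CHANNELS, CONDITIONS

__all__ = [
    "ConditionEffects",
    "SubjectSpread",
    "CohortSpec",
    "GroundTruth",
    "RecordingSession",
    "EcgParams",
    "EdaParams",
    "EmgParams",
    "generate_ecg",
    "generate_eda",
    "generate_emg",
    "generate_cohort",
    "scaled_down_spec",
    "save_session_csv",
    "load_session_csv",
    "save_cohort_hdf5",
    "load_cohort_hdf5",
]

# Fixed P-QRS-T beat template: (time offset from R in s, amplitude in mV,
# Gaussian sigma in s).  Only the T amplitude is parameterized.
_BEAT_TEMPLATE = (
    ("P", -0.200, 0.15, 0.025),
    ("Q", -0.035, -0.12, 0.012),
    ("R", 0.000, 1.10, 0.012),
    ("S", 0.035, -0.18, 0.012),
)
_T_OFFSET_S = 0.28
_T_SIGMA_S = 0.05

_LF_HZ = 0.1  # low-frequency RR modulation (Mayer-wave band)
_HF_HZ = 0.25  # high-frequency RR modulation (respiratory band)

_SCR_RISE_S = 0.75
_SCR_DECAY_S = 4.0


@dataclass(frozen=True)
class ConditionEffects:
    """Population-mean generator parameters for one emotional condition."""

    hr_bpm: float
    a_lf_s: float
    a_hf_s: float
    t_amp_mv: float
    t_jitter_mv: float
    scr_rate_per_min: float
    tonic_us: float
    emg_z_burst_rate_per_min: float
    emg_mf_burst_rate_per_min: float


#: Defaults chosen as plausible film-viewing physiology: fear raises heart
#: rate, SCR rate, T-wave spread and frontalis activity; happiness raises
#: zygomaticus activity; neutral is the low-arousal reference.
DEFAULT_EFFECTS: dict[str, ConditionEffects] = {
    "neutral": ConditionEffects(65.0, 0.020, 0.030, 0.30, 0.010, 2.0, 2.0, 3.0, 3.0),
    "fear": ConditionEffects(78.0, 0.040, 0.020, 0.36, 0.050, 6.0, 3.5, 4.0, 10.0),
    "happy": ConditionEffects(72.0, 0.030, 0.040, 0.33, 0.020, 4.0, 2.8, 10.0, 4.0),
}


@dataclass(frozen=True)
class SubjectSpread:
    """Between-subject standard deviations of the idiosyncratic offsets.

    Emotions are idiosyncratic: these spreads are comparable to the
    between-condition effect gaps, which is what makes the
    subject-independent split genuinely harder than the
    subject-dependent one."""

    hr_bpm: float = 6.0
    t_amp_mv: float = 0.06
    tonic_us: float = 0.8
    scr_rate_per_min: float = 1.5
    burst_rate_per_min: float = 1.5


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``channel_lags_s`` maps channel names to an integer-second offset
    added to that channel's hotspot onset (positive = later).
    """

    n_subjects: int = 55
    conditions: tuple[str, ...] = CONDITIONS
    session_minutes: float = 30.0
    fs: float = 1000.0
    hotspot_start_s: float = 600.0
    hotspot_len_s: float = 300.0
    hotspot_factor: float = 3.0
    arousal_amplitude: float = 0.8
    arousal_timescale_s: float = 3.0
    channel_lags_s: dict[str, int] = field(default_factory=dict)
    effects: dict[str, ConditionEffects] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    subject_sd: SubjectSpread = field(default_factory=SubjectSpread)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        dur = self.session_minutes * 60.0
        if dur < self.hotspot_len_s:
            raise ValueError("session shorter than hotspot length")
        for ch, lag in self.channel_lags_s.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            start = self.hotspot_start_s + lag
            if start < 0 or start + self.hotspot_len_s > dur:
                raise ValueError(f"hotspot for {ch!r} falls outside the session")
        if not (0 <= self.hotspot_start_s <= dur - self.hotspot_len_s):
            raise ValueError("hotspot interval not inside session")
        for cond, eff in self.effects.items():
            if eff.scr_rate_per_min < 0 or eff.emg_z_burst_rate_per_min < 0 \
                    or eff.emg_mf_burst_rate_per_min < 0:
                raise ValueError(f"negative rate in effects[{cond!r}]")

    @property
    def duration_s(self) -> float:
        return self.session_minutes * 60.0


def scaled_down_spec(
    n_subjects: int = 12,
    session_minutes: float = 12.0,
    hotspot_start_s: float = 240.0,
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Desk-scale cohort: 12 subjects x 3 conditions x 12-min sessions
    with the 5-min hotspot spanning minutes 4-9."""
    return CohortSpec(
        n_subjects=n_subjects,
        session_minutes=session_minutes,
        hotspot_start_s=hotspot_start_s,
        seed=seed,
        **kwargs,
    )


@dataclass
class GroundTruth:
    """Generator bookkeeping attached to each session."""

    r_peak_times: np.ndarray
    scr_event_times: np.ndarray
    emg_burst_intervals: dict[str, list[tuple[float, float]]]
    hotspot: dict[str, tuple[float, float]]
    params: dict

    def validate(self, duration_s: float) -> None:
        for name, times in (("r_peak", self.r_peak_times),
                            ("scr", self.scr_event_times)):
            t = np.asarray(times)
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > duration_s):
                raise ValueError(f"{name} times not strictly increasing in-session")


@dataclass
class RecordingSession:
    """One subject x condition multi-channel recording plus ground truth."""

    subject_id: str
    condition: str
    fs: float
    channels: dict[str, np.ndarray]
    ground_truth: GroundTruth

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("channels have unequal lengths")
        for name, x in self.channels.items():
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {name!r} contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(next(iter(self.channels.values()))) / self.fs


# ---------------------------------------------------------------------------
# per-channel generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcgParams:
    """``modulation``, when given, is a per-second rate/variability
    multiplier (already including the hotspot activation factor); it
    scales the LF/HF RR modulation amplitudes and — through
    ``hr_mod_gain`` — the instantaneous heart rate, since beats are the
    information-carrying events of the ECG channel.  Without it the
    ``hotspot``/``hotspot_factor`` pair provides a piecewise-constant
    fallback."""

    mean_hr_bpm: float
    a_lf_s: float = 0.0
    a_hf_s: float = 0.0
    rr_jitter_s: float = 0.005
    t_amp_mv: float = 0.30
    t_jitter_mv: float = 0.0
    noise_mv: float = 0.01
    hotspot: tuple[float, float] | None = None
    hotspot_factor: float = 1.0
    modulation: np.ndarray | None = None
    hr_mod_gain: float = 0.1


@dataclass(frozen=True)
class EdaParams:
    tonic_us: float
    scr_rate_per_min: float
    tonic_drift_us: float = 0.01
    scr_amp_us: float = 0.4
    scr_amp_sd_us: float = 0.15
    noise_us: float = 0.005
    hotspot: tuple[float, float] | None = None
    hotspot_factor: float = 1.0
    modulation: np.ndarray | None = None


@dataclass(frozen=True)
class EmgParams:
    burst_rate_per_min: float
    baseline_rms_mv: float = 0.02
    burst_amp_factor: float = 10.0
    burst_len_s: float = 0.5
    hotspot: tuple[float, float] | None = None
    hotspot_factor: float = 1.0
    modulation: np.ndarray | None = None


def _modulation_at(params, t: float | np.ndarray):
    """Per-second activation multiplier at time(s) ``t``: the explicit
    modulation curve when present, else the hotspot step function."""
    if params.modulation is not None:
        mod = np.asarray(params.modulation, dtype=float)
        idx = np.clip(np.asarray(t, dtype=int), 0, mod.size - 1)
        return mod[idx]
    inside = _in_interval(t, params.hotspot)
    return np.where(inside, params.hotspot_factor, 1.0)


def _check_duration(duration_s: float, fs: float) -> int:
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    return int(round(duration_s * fs))


def _in_interval(t: np.ndarray | float, interval: tuple[float, float] | None):
    if interval is None:
        return np.zeros_like(np.asarray(t, dtype=float), dtype=bool)
    lo, hi = interval
    return (np.asarray(t) >= lo) & (np.asarray(t) < hi)


def generate_ecg(
    params: EcgParams, duration_s: float, fs: float, rng: Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize an ECG channel; returns ``(signal_mv, r_peak_times_s)``.

    Beats are placed on an RR schedule ``mean_RR + A_LF sin(2π 0.1 t)
    + A_HF sin(2π 0.25 t) + jitter`` and rendered with a fixed sum-of-
    Gaussians P-QRS-T template whose T amplitude (plus optional
    beat-to-beat jitter) comes from ``params``.  The activation
    modulation (hotspot step and/or arousal curve) scales the LF/HF
    modulation amplitudes and mildly raises the instantaneous heart
    rate (``hr_mod_gain``)."""
    n = _check_duration(duration_s, fs)
    if not (30.0 <= params.mean_hr_bpm <= 200.0):
        raise ValueError("mean HR must be in [30, 200] bpm")
    mean_rr = 60.0 / params.mean_hr_bpm

    beats = []
    t = 0.3  # first beat shortly after session start
    while t < duration_s - _T_OFFSET_S - 3 * _T_SIGMA_S:
        beats.append(t)
        boost = float(_modulation_at(params, t))
        hr_scale = 1.0 + params.hr_mod_gain * (boost - 1.0)
        rr = (
            mean_rr / max(hr_scale, 0.5)
            + boost * params.a_lf_s * np.sin(2 * np.pi * _LF_HZ * t)
            + boost * params.a_hf_s * np.sin(2 * np.pi * _HF_HZ * t)
        )
        if params.rr_jitter_s > 0:
            rr += params.rr_jitter_s * rng.standard_normal()
        t += max(rr, 0.3)
    r_times = np.asarray(beats)

    x = np.zeros(n)
    tt = np.arange(n) / fs
    half = int(round(0.45 * fs))
    for bt in r_times:
        amp_t = params.t_amp_mv
        if params.t_jitter_mv > 0:
            amp_t += params.t_jitter_mv * rng.standard_normal()
        i0 = max(int(round((bt - 0.30) * fs)), 0)
        i1 = min(i0 + half + int(round(0.30 * fs)), n)
        seg = tt[i0:i1] - bt
        wave = np.zeros_like(seg)
        for _, off, amp, sig in _BEAT_TEMPLATE:
            wave += amp * np.exp(-0.5 * ((seg - off) / sig) ** 2)
        wave += amp_t * np.exp(-0.5 * ((seg - _T_OFFSET_S) / _T_SIGMA_S) ** 2)
        x[i0:i1] += wave
    if params.noise_mv > 0:
        x += params.noise_mv * rng.standard_normal(n)
    return x, r_times


def _poisson_events(params, rate_per_min: float, duration_s: float,
                    rng: Generator) -> np.ndarray:
    """Inhomogeneous Poisson event times via thinning; the rate is
    multiplied by the activation modulation (hotspot factor and, when
    configured, the session arousal curve)."""
    base = rate_per_min / 60.0
    if base <= 0:
        return np.empty(0)
    grid = _modulation_at(params, np.arange(int(np.ceil(duration_s))))
    peak = base * max(float(np.max(grid)), 1.0)
    n = rng.poisson(peak * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n))
    rate = base * _modulation_at(params, cand)
    keep = rng.uniform(0.0, peak, size=n) < rate
    times = cand[keep]
    # strict monotonicity for ground-truth invariants
    return np.unique(times)


def generate_eda(
    params: EdaParams, duration_s: float, fs: float, rng: Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize an EDA channel; returns ``(signal_us, scr_event_times_s)``.

    Tonic component: slow random walk around ``tonic_us``.  Phasic
    component: unit-peak bi-exponential SCR shapes (rise 0.75 s, decay
    4 s) at Poisson event times whose rate is multiplied by
    ``hotspot_factor`` inside the hotspot.
    """
    n = _check_duration(duration_s, fs)
    if params.scr_rate_per_min < 0:
        raise ValueError("scr_rate must be >= 0")
    n_sec = int(np.ceil(duration_s)) + 1
    walk = np.cumsum(params.tonic_drift_us * rng.standard_normal(n_sec))
    tonic = params.tonic_us + np.interp(np.arange(n) / fs, np.arange(n_sec), walk)

    events = _poisson_events(params, params.scr_rate_per_min, duration_s, rng)
    x = tonic
    if events.size:
        klen = int(round(25.0 * fs))
        kt = np.arange(klen) / fs
        kernel = np.exp(-kt / _SCR_DECAY_S) - np.exp(-kt / _SCR_RISE_S)
        kernel /= kernel.max()
        phasic = np.zeros(n)
        for ev in events:
            amp = max(params.scr_amp_us + params.scr_amp_sd_us * rng.standard_normal(),
                      0.05)
            i0 = int(round(ev * fs))
            i1 = min(i0 + klen, n)
            phasic[i0:i1] += amp * kernel[: i1 - i0]
        x = x + phasic
    if params.noise_us > 0:
        x = x + params.noise_us * rng.standard_normal(n)
    return x, events


def generate_emg(
    params: EmgParams, duration_s: float, fs: float, rng: Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a surface-EMG channel; returns ``(signal_mv, bursts)``
    where ``bursts`` is an ``(n, 2)`` array of (start, end) times.

    Baseline is Gaussian noise band-limited to 20-450 Hz; bursts
    amplitude-modulate it by ``burst_amp_factor`` under a Hann envelope
    at Poisson onset times (rate boosted inside the hotspot).  Bursts
    are kept non-overlapping (later colliding onsets are dropped) so the
    returned intervals are an exact event-count ground truth.
    """
    from scipy.signal import butter, sosfiltfilt

    n = _check_duration(duration_s, fs)
    if params.burst_rate_per_min < 0:
        raise ValueError("burst rate must be >= 0")
    if fs <= 900.0:
        raise ValueError("fs too low for a 20-450 Hz EMG band")
    sos = butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    noise = sosfiltfilt(sos, rng.standard_normal(n))
    noise *= params.baseline_rms_mv / max(np.std(noise), 1e-12)

    onsets = _poisson_events(params, params.burst_rate_per_min, duration_s, rng)
    intervals: list[tuple[float, float]] = []
    last_end = -1.0
    for on in onsets:
        length = params.burst_len_s * float(np.exp(0.3 * rng.standard_normal()))
        end = min(on + max(length, 0.15), duration_s)
        if on <= last_end + 0.5:  # enforce separability of bursts
            continue
        intervals.append((float(on), float(end)))
        last_end = end
    gain = np.ones(n)
    for on, end in intervals:
        i0, i1 = int(round(on * fs)), int(round(end * fs))
        gain[i0:i1] += (params.burst_amp_factor - 1.0) * np.hanning(i1 - i0)
    x = noise * gain
    return x, np.asarray(intervals).reshape(-1, 2)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _params_dict(params) -> dict:
    d = dataclasses.asdict(params)
    d.pop("modulation", None)  # the 1-Hz curve is stored once per session
    return d


def _subject_offsets(sd: SubjectSpread, rng: Generator) -> dict[str, float]:
    return {
        "hr_bpm": sd.hr_bpm * rng.standard_normal(),
        "t_amp_mv": sd.t_amp_mv * rng.standard_normal(),
        "tonic_us": sd.tonic_us * rng.standard_normal(),
        "scr_rate_per_min": sd.scr_rate_per_min * rng.standard_normal(),
        "burst_rate_per_min": sd.burst_rate_per_min * rng.standard_normal(),
    }


def _arousal_curve(spec: CohortSpec, rng: Generator) -> np.ndarray:
    """Session-level activation time course at 1 Hz, shared by all
    channels: a smooth unit-mean curve that multiplies event rates.  It
    emulates the common slow arousal dynamics that make the per-channel
    information profiles co-vary (the premise of the cross-correlation
    synchronization stage)."""
    n = int(np.ceil(spec.duration_s)) + 1
    z = rng.standard_normal(n)
    sigma = max(spec.arousal_timescale_s, 1.0)
    klen = int(6 * sigma) | 1
    kt = np.arange(klen) - klen // 2
    kernel = np.exp(-0.5 * (kt / sigma) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np.pad(z, klen, mode="reflect"), kernel,
                         mode="same")[klen:klen + n]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.maximum(1.0 + spec.arousal_amplitude * smooth, 0.2)


def _channel_modulation(spec: CohortSpec, arousal: np.ndarray,
                        channel: str) -> np.ndarray:
    """Arousal curve delayed by the channel lag, times the hotspot step."""
    lag = spec.channel_lags_s.get(channel, 0)
    t = np.arange(arousal.size)
    shifted = arousal[np.clip(t - lag, 0, arousal.size - 1)]
    start = spec.hotspot_start_s + lag
    inside = (t >= start) & (t < start + spec.hotspot_len_s)
    return shifted * np.where(inside, spec.hotspot_factor, 1.0)


def _session_params(
    spec: CohortSpec, condition: str, offs: dict[str, float],
    arousal: np.ndarray,
) -> dict[str, object]:
    eff = spec.effects[condition]
    hs = {
        ch: (
            spec.hotspot_start_s + spec.channel_lags_s.get(ch, 0),
            spec.hotspot_start_s + spec.channel_lags_s.get(ch, 0)
            + spec.hotspot_len_s,
        )
        for ch in CHANNELS
    }
    mods = {ch: _channel_modulation(spec, arousal, ch) for ch in CHANNELS}
    ecg = EcgParams(
        mean_hr_bpm=float(np.clip(eff.hr_bpm + offs["hr_bpm"], 40.0, 180.0)),
        a_lf_s=eff.a_lf_s,
        a_hf_s=eff.a_hf_s,
        t_amp_mv=max(eff.t_amp_mv + offs["t_amp_mv"], 0.05),
        t_jitter_mv=eff.t_jitter_mv,
        hotspot=hs["ecg"],
        hotspot_factor=spec.hotspot_factor,
        modulation=mods["ecg"],
    )
    eda = EdaParams(
        tonic_us=max(eff.tonic_us + offs["tonic_us"], 0.2),
        scr_rate_per_min=max(eff.scr_rate_per_min + offs["scr_rate_per_min"], 0.0),
        hotspot=hs["eda"],
        hotspot_factor=spec.hotspot_factor,
        modulation=mods["eda"],
    )
    emg_z = EmgParams(
        burst_rate_per_min=max(
            eff.emg_z_burst_rate_per_min + offs["burst_rate_per_min"], 0.0
        ),
        hotspot=hs["emg_z"],
        hotspot_factor=spec.hotspot_factor,
        modulation=mods["emg_z"],
    )
    emg_mf = EmgParams(
        burst_rate_per_min=max(
            eff.emg_mf_burst_rate_per_min + offs["burst_rate_per_min"], 0.0
        ),
        hotspot=hs["emg_mf"],
        hotspot_factor=spec.hotspot_factor,
        modulation=mods["emg_mf"],
    )
    return {"ecg": ecg, "eda": eda, "emg_z": emg_z, "emg_mf": emg_mf,
            "hotspot": hs, "arousal": arousal}


def generate_cohort(spec: CohortSpec) -> list[RecordingSession]:
    """Generate ``n_subjects x len(conditions)`` sessions.

    Subject-level idiosyncratic offsets are drawn once per subject and
    shared across that subject's conditions; the full cohort is a
    deterministic function of ``spec.seed``.
    """
    dur, fs = spec.duration_s, spec.fs
    subject_seqs = SeedSequence(spec.seed).spawn(spec.n_subjects)
    sessions: list[RecordingSession] = []
    for si, sseq in enumerate(subject_seqs):
        streams = sseq.spawn(len(spec.conditions) + 1)
        offs = _subject_offsets(spec.subject_sd, default_rng(streams[0]))
        for ci, cond in enumerate(spec.conditions):
            rng = default_rng(streams[ci + 1])
            arousal = _arousal_curve(spec, rng)
            p = _session_params(spec, cond, offs, arousal)
            ecg, r_times = generate_ecg(p["ecg"], dur, fs, rng)
            eda, scr_times = generate_eda(p["eda"], dur, fs, rng)
            emg_z, bursts_z = generate_emg(p["emg_z"], dur, fs, rng)
            emg_mf, bursts_mf = generate_emg(p["emg_mf"], dur, fs, rng)
            gt = GroundTruth(
                r_peak_times=r_times,
                scr_event_times=scr_times,
                emg_burst_intervals={
                    "emg_z": [tuple(b) for b in bursts_z],
                    "emg_mf": [tuple(b) for b in bursts_mf],
                },
                hotspot=p["hotspot"],
                params={
                    "subject_offsets": offs,
                    "arousal_1hz": np.asarray(p["arousal"]).tolist(),
                    **{ch: _params_dict(p[ch]) for ch in CHANNELS},
                },
            )
            gt.validate(dur)
            sessions.append(
                RecordingSession(
                    subject_id=f"S{si:02d}",
                    condition=cond,
                    fs=fs,
                    channels={"ecg": ecg, "eda": eda,
                              "emg_z": emg_z, "emg_mf": emg_mf},
                    ground_truth=gt,
                )
            )
    return sessions


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _gt_to_jsonable(gt: GroundTruth) -> dict:
    return {
        "r_peak_times": np.asarray(gt.r_peak_times).tolist(),
        "scr_event_times": np.asarray(gt.scr_event_times).tolist(),
        "emg_burst_intervals": {
            k: [list(map(float, iv)) for iv in v]
            for k, v in gt.emg_burst_intervals.items()
        },
        "hotspot": {k: list(map(float, v)) for k, v in gt.hotspot.items()},
        "params": json.loads(json.dumps(gt.params, default=float)),
    }


def _gt_from_jsonable(d: dict) -> GroundTruth:
    return GroundTruth(
        r_peak_times=np.asarray(d["r_peak_times"]),
        scr_event_times=np.asarray(d["scr_event_times"]),
        emg_burst_intervals={
            k: [tuple(iv) for iv in v] for k, v in d["emg_burst_intervals"].items()
        },
        hotspot={k: tuple(v) for k, v in d["hotspot"].items()},
        params=d["params"],
    )


def save_session_csv(session: RecordingSession, path: str | Path) -> None:
    """Write one session as a delimited text file (time_s + channels)
    with a JSON ground-truth sidecar at ``<path>.truth.json``."""
    path = Path(path)
    n = len(session.channels["ecg"])
    cols = [np.arange(n) / session.fs] + [session.channels[c] for c in CHANNELS]
    header = "time_s," + ",".join(CHANNELS)
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="", fmt="%.6f")
    meta = {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "fs": session.fs,
        "ground_truth": _gt_to_jsonable(session.ground_truth),
    }
    Path(str(path) + ".truth.json").write_text(json.dumps(meta))


def load_session_csv(path: str | Path) -> RecordingSession:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = json.loads(Path(str(path) + ".truth.json").read_text())
    channels = {c: data[:, i + 1].copy() for i, c in enumerate(CHANNELS)}
    return RecordingSession(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        fs=meta["fs"],
        channels=channels,
        ground_truth=_gt_from_jsonable(meta["ground_truth"]),
    )


def save_cohort_hdf5(sessions: list[RecordingSession], path: str | Path) -> None:
    """Write a cohort as one HDF5 container, one group per session."""
    with h5py.File(path, "w") as f:
        for s in sessions:
            g = f.create_group(f"{s.subject_id}/{s.condition}")
            g.attrs["fs"] = s.fs
            for c in CHANNELS:
                g.create_dataset(c, data=s.channels[c], compression="gzip")
            g.attrs["ground_truth"] = json.dumps(_gt_to_jsonable(s.ground_truth))


def load_cohort_hdf5(path: str | Path) -> list[RecordingSession]:
    sessions = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            for cond in f[sid]:
                g = f[sid][cond]
                sessions.append(
                    RecordingSession(
                        subject_id=sid,
                        condition=cond,
                        fs=float(g.attrs["fs"]),
                        channels={c: g[c][()] for c in CHANNELS},
                        ground_truth=_gt_from_jsonable(
                            json.loads(g.attrs["ground_truth"])
                        ),
                    )
                )
    return sessions
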