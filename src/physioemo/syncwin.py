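"""Cross-channel synchronization and maximal-information window selection.

The four per-second information profiles of a session are expected to
co-vary, since all channels respond to the same stimulus.  A channel may
nevertheless lag the others by a few seconds; the optimal integer-second
lag is estimated by normalized cross-correlation against a reference
channel (ECG by default) and removed by shifting the profile left when
the optimal lag is positive and right when negative, trimming all
channels to the common overlap.  The 5-min window with the highest total
information is then found by z-scoring each synchronized profile,
summing across channels and sliding a 300-s window at 1-s steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LagResult",
    "SyncResult",
    "WindowSelection",
    "smooth_profile",
    "optimal_lag",
    "synchronize",
    "select_window",
]

DEFAULT_MAX_LAG_S = 120
DEFAULT_WINDOW_S = 300


@dataclass(frozen=True)
class LagResult:
    """Optimal lag of one profile relative to another.

    A positive ``lag_s`` means the second profile is delayed by that many
    seconds.  ``degenerate`` flags a zero-variance input, for which the
    correlation is undefined and lag 0 is returned.
    """

    lag_s: int
    peak_correlation: float
    degenerate: bool = False


@dataclass
class SyncResult:
    """Profiles shifted to a common timeline.

    ``channel_offsets[c]`` maps a synchronized-time index ``t`` to the
    original index ``t + channel_offsets[c]`` of channel ``c``.
    """

    profiles: dict[str, np.ndarray]
    lags: dict[str, LagResult]
    reference: str
    channel_offsets: dict[str, int]


@dataclass
class WindowSelection:
    """Start of the selected window on the synchronized timeline plus the
    per-channel offsets needed to cut it from the original signals."""

    start_s: int
    length_s: int = DEFAULT_WINDOW_S
    channel_offsets: dict[str, int] = field(default_factory=dict)

    def channel_start_s(self, channel: str) -> int:
        return self.start_s + self.channel_offsets.get(channel, 0)


def smooth_profile(profile: np.ndarray, window_s: int = 3) -> np.ndarray:
    """Moving-average smoothing (reflect-padded, length-preserving) that
    suppresses per-second shot noise before lag estimation."""
    p = np.asarray(profile, dtype=float)
    if window_s <= 1:
        return p
    k = np.ones(window_s) / window_s
    return np.convolve(np.pad(p, window_s, mode="reflect"), k,
                       mode="same")[window_s:-window_s]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def optimal_lag(profile_a: np.ndarray, profile_b: np.ndarray,
                max_lag_s: int = DEFAULT_MAX_LAG_S) -> LagResult:
    """Lag of ``profile_b`` relative to ``profile_a`` maximizing the
    normalized cross-correlation over lags in [-max_lag_s, +max_lag_s].

    Ties are broken toward smaller ``|lag|``, then toward the negative
    lag.  If either profile has zero variance the correlation is
    undefined and ``LagResult(0, 0.0, degenerate=True)`` is returned.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    n = min(a.size, b.size)
    if n < 2 * max_lag_s + 60:
        raise ValueError("profiles too short for the requested max lag")
    a, b = a[:n], b[:n]
    if a.std() == 0 or b.std() == 0:
        return LagResult(0, 0.0, degenerate=True)
    lags = sorted(range(-max_lag_s, max_lag_s + 1), key=lambda l: (abs(l), l))
    best_lag, best_corr = 0, -np.inf
    for lag in lags:
        if lag >= 0:
            corr = _pearson(a[: n - lag] if lag else a, b[lag:])
        else:
            corr = _pearson(a[-lag:], b[: n + lag])
        if corr > best_corr:
            best_lag, best_corr = lag, corr
    return LagResult(int(best_lag), float(best_corr))


def synchronize(profiles: dict[str, np.ndarray], reference: str = "ecg",
                max_lag_s: int = DEFAULT_MAX_LAG_S) -> SyncResult:
    """Shift every non-reference profile by the modulus of its optimal lag
    (left for positive lags, right for negative) and trim all channels to
    the common overlap."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 channels to synchronize")
    if reference not in profiles:
        raise ValueError(f"reference channel {reference!r} missing")
    ref = np.asarray(profiles[reference], dtype=float)
    lags: dict[str, LagResult] = {reference: LagResult(0, 1.0)}
    offsets: dict[str, int] = {reference: 0}
    for ch, prof in profiles.items():
        if ch == reference:
            continue
        res = optimal_lag(ref, prof, max_lag_s)
        lags[ch] = res
        offsets[ch] = res.lag_s
    # common synchronized-time range: t + offset must be a valid index
    t0 = max(0, max(-o for o in offsets.values()))
    t1 = min(len(np.asarray(profiles[ch])) - offsets[ch] for ch in profiles)
    if t1 - t0 < 1:
        raise ValueError("required shift exceeds profile length")
    shifted = {ch: np.asarray(profiles[ch], dtype=float)[t0 + offsets[ch]:
                                                         t1 + offsets[ch]]
               for ch in profiles}
    final_offsets = {ch: t0 + offsets[ch] for ch in profiles}
    return SyncResult(profiles=shifted, lags=lags, reference=reference,
                      channel_offsets=final_offsets)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def select_window(profiles: dict[str, np.ndarray] | SyncResult,
                  length_s: int = DEFAULT_WINDOW_S) -> WindowSelection:
    """Select the ``length_s`` window maximizing the summed z-scored
    information across channels (step 1 s; ties go to the earliest
    start).  Z-scoring keeps the highest-entropy channel from dominating
    and makes the choice invariant to per-channel constant offsets."""
    offsets: dict[str, int] = {}
    if isinstance(profiles, SyncResult):
        offsets = profiles.channel_offsets
        profiles = profiles.profiles
    arrs = [np.asarray(p, dtype=float) for p in profiles.values()]
    n = min(a.size for a in arrs)
    if n < length_s:
        raise ValueError("profiles shorter than the window length")
    total = np.sum([_zscore(a[:n]) for a in arrs], axis=0)
    csum = np.r_[0.0, np.cumsum(total)]
    window_sums = csum[length_s:] - csum[:-length_s]
    start = int(np.argmax(window_sums))  # argmax returns the earliest tie
    return WindowSelection(start_s=start, length_s=length_s,
                           channel_offsets=dict(offsets))
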