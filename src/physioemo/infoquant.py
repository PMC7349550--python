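"""Compression-based per-second information-quantity profiles (xaFCM).

An extended-alphabet finite-context model estimates, for each successive
block of ``d`` symbols, the probability of that block given the ``k``
preceding blocks (an order-``k`` context over the extended alphabet of
``A**d`` super-symbols).  The negative log2 of that probability is the
number of bits an adaptive arithmetic coder driven by the model would
emit for the block; summing block code lengths by the second in which
each block starts yields a per-second information profile.  High values
mark locally complex / novel signal, low values redundancy.

The model is adaptive: each block is first coded with the counts
accumulated so far, then counted.  Counts are Laplace-smoothed with a
pseudo-count ``alpha`` per outcome, so an unseen context codes every
block at the uniform ``d*log2(A)`` bits.  The model is reset per channel
per session so no information leaks across conditions.

Signals are discretized by clipping to configurable amplitude
percentiles and uniform binning into ``A`` levels, which makes the
profile invariant to affine amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "XafcmConfig",
    "ContextModel",
    "InformationProfile",
    "quantize",
    "block_bits",
    "information_profile",
    "signal_information_profile",
]


@dataclass(frozen=True)
class XafcmConfig:
    """Configuration of the extended-alphabet finite-context model.

    Defaults (A=8, k=2, d=1, alpha=1/A**d, 1-99 percentile clipping)
    keep the context table small enough (A**(k*d) contexts) for the
    adaptive counts to converge within minutes of 1000-Hz signal, so the
    per-second profile tracks local signal complexity rather than the
    model's own learning transient.
    """

    alphabet_size: int = 8
    order: int = 2
    depth: int = 1
    alpha: float | None = None
    clip_percentiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.order < 1:
            raise ValueError("context order k must be >= 1")
        if self.depth < 1:
            raise ValueError("depth d must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        lo, hi = self.clip_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("invalid clip percentiles")
        if self.alphabet_size ** ((self.order + 1) * self.depth) > 2 ** 62:
            raise ValueError("A**((k+1)*d) too large to enumerate")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 1.0 / self.n_outcomes

    @property
    def n_outcomes(self) -> int:
        """Number of extended-alphabet outcomes per context, A**d."""
        return self.alphabet_size ** self.depth


def quantize(x: np.ndarray, config: XafcmConfig) -> np.ndarray:
    """Percentile-clip and uniformly bin amplitudes into ``A`` symbols."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot quantize an empty signal")
    lo, hi = np.percentile(x, config.clip_percentiles)
    if hi <= lo:  # constant signal: everything in one bin
        return np.zeros(x.size, dtype=np.int64)
    xc = np.clip(x, lo, hi)
    sym = np.floor((xc - lo) / (hi - lo) * config.alphabet_size).astype(np.int64)
    return np.minimum(sym, config.alphabet_size - 1)


@dataclass
class ContextModel:
    """Adaptive count table: context (tuple of k*d symbols) -> counts over
    the A**d possible next blocks."""

    config: XafcmConfig
    counts: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)
    total_updates: int = 0

    def _block_code(self, block) -> int:
        code = 0
        for s in block:
            code = code * self.config.alphabet_size + int(s)
        return code

    def context_counts(self, context) -> np.ndarray:
        key = tuple(int(s) for s in context)
        return self.counts.get(key, np.zeros(self.config.n_outcomes, dtype=np.int64))

    def update(self, context, block) -> None:
        key = tuple(int(s) for s in context)
        if key not in self.counts:
            self.counts[key] = np.zeros(self.config.n_outcomes, dtype=np.int64)
        self.counts[key][self._block_code(block)] += 1
        self.total_updates += 1


def block_bits(model: ContextModel, context, block, alpha: float | None = None
               ) -> float:
    """Code length in bits of ``block`` under ``model`` given ``context``.

    Returns ``-log2[(c + alpha) / (C + alpha * A**d)]`` where ``c`` is the
    count of (context, block) and ``C`` the total count of the context.
    Does not mutate the model; an unseen context therefore codes at the
    uniform ``d * log2(A)`` bits.
    """
    cfg = model.config
    if len(tuple(context)) != cfg.order * cfg.depth:
        raise ValueError("context must have k*d symbols")
    if len(tuple(block)) != cfg.depth:
        raise ValueError("block must have d symbols")
    a = cfg.effective_alpha if alpha is None else alpha
    cc = model.context_counts(context)
    c = float(cc[model._block_code(block)])
    total = float(cc.sum())
    return float(-np.log2((c + a) / (total + a * cfg.n_outcomes)))


@dataclass
class InformationProfile:
    """Per-second code length (bits) of one channel."""

    bits_per_second: np.ndarray
    channel: str
    config: XafcmConfig

    def __post_init__(self) -> None:
        b = np.asarray(self.bits_per_second, dtype=float)
        if np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValueError("profile values must be finite and >= 0")
        self.bits_per_second = b

    def __len__(self) -> int:
        return len(self.bits_per_second)


def _prior_occurrence_counts(keys: np.ndarray) -> np.ndarray:
    """For each element, the number of earlier elements with the same key.

    Grouped cumulative count via a stable argsort; exact equivalent of a
    sequential dictionary update.
    """
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    n = sk.size
    new_group = np.r_[True, sk[1:] != sk[:-1]]
    group_start = np.flatnonzero(new_group)
    sizes = np.diff(np.r_[group_start, n])
    rank_in_group = np.arange(n) - np.repeat(group_start, sizes)
    out = np.empty(n, dtype=np.int64)
    out[order] = rank_in_group
    return out


def information_profile(symbols: np.ndarray, fs: float,
                        config: XafcmConfig) -> InformationProfile:
    """Single adaptive pass over a symbol sequence.

    Blocks of ``d`` symbols start at index ``k*d`` (the first position
    with a full context) and step by ``d``; each block is coded with the
    counts accumulated so far, then counted.  Per-second values sum the
    code lengths of blocks whose start falls in that second; the final
    partial second is dropped.
    """
    sym = np.asarray(symbols, dtype=np.int64)
    fs_i = int(round(fs))
    if fs_i <= 0:
        raise ValueError("fs must be positive")
    if sym.size < fs_i:
        raise ValueError("need at least one second of symbols")
    A, k, d = config.alphabet_size, config.order, config.depth
    if np.any(sym < 0) or np.any(sym >= A):
        raise ValueError("symbols outside alphabet")
    if k * d > fs_i:
        raise ValueError("context k*d longer than one second of symbols")
    a = config.effective_alpha

    n_blocks = (sym.size - k * d) // d
    if n_blocks < 1:
        raise ValueError("sequence too short for a single block")
    starts = k * d + d * np.arange(n_blocks, dtype=np.int64)

    block_code = np.zeros(n_blocks, dtype=np.int64)
    for j in range(d):
        block_code = block_code * A + sym[starts + j]
    ctx_code = np.zeros(n_blocks, dtype=np.int64)
    for j in range(k * d):
        ctx_code = ctx_code * A + sym[starts - k * d + j]

    n_out = A ** d
    pair_code = ctx_code * n_out + block_code
    c_pair = _prior_occurrence_counts(pair_code)
    c_ctx = _prior_occurrence_counts(ctx_code)
    bits = -np.log2((c_pair + a) / (c_ctx + a * n_out))

    n_sec = sym.size // fs_i
    sec = starts // fs_i
    keep = sec < n_sec
    per_sec = np.bincount(sec[keep], weights=bits[keep], minlength=n_sec)
    return InformationProfile(per_sec, channel="", config=config)


def signal_information_profile(x: np.ndarray, fs: float, config: XafcmConfig,
                               channel: str = "") -> InformationProfile:
    """Quantize a raw signal and compute its information profile."""
    prof = information_profile(quantize(x, config), fs, config)
    prof.channel = channel
    return prof
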