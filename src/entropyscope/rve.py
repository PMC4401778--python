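"""Rank vector entropy (RVE): a time-resolved, amplitude-free entropy measure.

A sliding window of ``W`` samples taken at lag ``xi`` is reduced to its rank
vector (the ordinal pattern of the samples), which indexes one of ``W!``
symbols.  A leaky integrator accumulates symbol frequencies — every count
decays by ``alpha = exp(-1/(f*tau))`` per step before the current symbol is
incremented — and the normalised Shannon entropy of the resulting
distribution is emitted at every sample:

    S(k) = (1 / ln W!) * sum_n -p_n(k) ln p_n(k)

S is bounded in [0, 1]: 1 when all ordinal patterns are equally frequent
(e.g. exchangeable noise), near 0 for a signal stuck in few patterns.
Because only ranks enter, S is invariant under any strictly increasing
pointwise transform of the input — in particular under amplitude scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .paradigms import ParadigmSpec

__all__ = [
    "RveConfig",
    "SymbolTable",
    "SymbolHistogram",
    "EntropyTimecourse",
    "extract_rank_vector",
    "symbolise",
    "update_histogram",
    "entropy",
    "rve_timecourse",
    "trial_average_entropy",
]


@dataclass(frozen=True)
class RveConfig:
    """Parameters of the rank-vector-entropy transform.

    tau is the leaky-integrator time constant in seconds: the time for a
    symbol count to decay to 1/e of its value.  burn_in masks the initial
    stretch during which the histogram is still filling (default 3*tau).
    """

    W: int = 5
    xi: int = 2
    tau: float = 0.3
    f: float = 600.0
    burn_in: float | None = None

    def __post_init__(self) -> None:
        if self.W < 2:
            raise ValueError("W must be >= 2")
        if self.xi < 1:
            raise ValueError("xi must be >= 1")
        if self.tau <= 0 or self.f <= 0:
            raise ValueError("tau and f must be positive")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", 3.0 * self.tau)

    @property
    def alpha(self) -> float:
        """Per-sample decay factor, exp(-1/(f*tau))."""
        return math.exp(-1.0 / (self.f * self.tau))

    @property
    def span(self) -> int:
        """Number of input samples covered by one window: (W-1)*xi + 1."""
        return (self.W - 1) * self.xi + 1


class SymbolTable:
    """Bijection between the W! rank vectors and symbol indices 1..W!.

    The enumeration is lexicographic, so [1, 2, ..., W] maps to symbol 1 and
    the fully reversed vector to symbol W!.
    """

    def __init__(self, W: int):
        if W < 2:
            raise ValueError("W must be >= 2")
        self.W = W
        self.size = math.factorial(W)
        # factorial number system place values for Lehmer encoding
        self._places = np.array([math.factorial(W - 1 - i) for i in range(W)],
                                dtype=np.int64)

    def symbol(self, rank_vector: np.ndarray) -> int:
        """Lexicographic index (1-based) of a permutation of 1..W."""
        rv = np.asarray(rank_vector)
        if sorted(rv.tolist()) != list(range(1, self.W + 1)):
            raise ValueError(f"not a permutation of 1..{self.W}: {rank_vector}")
        return int(self._symbols_from_ranks(rv[None, :] - 1)[0]) + 1

    def _symbols_from_ranks(self, ranks0: np.ndarray) -> np.ndarray:
        """Vectorised Lehmer codes for an (n, W) array of 0-based permutations."""
        n, W = ranks0.shape
        lehmer = np.zeros((n, W), dtype=np.int64)
        for i in range(W):
            # count of later entries smaller than entry i
            lehmer[:, i] = np.sum(ranks0[:, i + 1:] < ranks0[:, i:i + 1], axis=1)
        return lehmer @ self._places  # 0-based symbol


@dataclass
class SymbolHistogram:
    """Leaky symbol-frequency state: non-negative counts F and probabilities F/sum(F)."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if np.any(self.F < 0):
            raise ValueError("frequencies must be non-negative")

    @property
    def P(self) -> np.ndarray:
        total = self.F.sum()
        if total <= 0:
            raise ValueError("entropy undefined for an all-zero histogram")
        return self.F / total


@dataclass
class EntropyTimecourse:
    """Entropy samples S in [0, 1] with a burn-in mask and provenance config.

    S[k] is timestamped at the first sample of window k; the timecourse is
    shorter than the input by (W-1)*xi samples.
    """

    S: np.ndarray
    sampling_rate: float
    burn_in_mask: np.ndarray  # True where the histogram is still filling
    config: RveConfig

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.S.size) / self.sampling_rate

    def valid(self) -> np.ndarray:
        return self.S[~self.burn_in_mask]


def extract_rank_vector(window_values: np.ndarray) -> np.ndarray:
    """Rank vector of a window: element j is the (1-based) index of the
    j-th smallest value; ties broken by the earlier index (stable)."""
    w = np.asarray(window_values, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return np.argsort(w, kind="stable") + 1


def symbolise(rank_vector: np.ndarray, table: SymbolTable) -> int:
    """Symbol index in [1, W!] of a rank vector under the lexicographic table."""
    return table.symbol(rank_vector)


def update_histogram(hist: SymbolHistogram, symbol: int, alpha: float) -> SymbolHistogram:
    """Decay all counts by alpha, then increment the observed symbol (1-based).

    With alpha = 1 this reduces to plain cumulative counting.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    F = alpha * hist.F
    F[symbol - 1] += 1.0
    return SymbolHistogram(F)


def entropy(hist: SymbolHistogram, W: int) -> float:
    """Normalised Shannon entropy of the histogram, in [0, 1]."""
    p = hist.P
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(math.factorial(W)))


def _symbol_sequence(x: np.ndarray, cfg: RveConfig) -> np.ndarray:
    """0-based symbol at every window position (vectorised symbolisation)."""
    x = np.asarray(x, dtype=float)
    n_windows = x.size - (cfg.W - 1) * cfg.xi
    idx = np.arange(n_windows)[:, None] + cfg.xi * np.arange(cfg.W)[None, :]
    windows = x[idx]
    ranks0 = np.argsort(windows, axis=1, kind="stable")
    table = SymbolTable(cfg.W)
    return table._symbols_from_ranks(ranks0)


def rve_timecourse(x: np.ndarray, cfg: RveConfig) -> EntropyTimecourse:
    """Full RVE transform of a 1-D timecourse.

    The window slides by one sample; at each position the symbol is fed to the
    leaky histogram and the normalised entropy of the current distribution is
    emitted.  The recursion F_k = alpha*F_{k-1} + e_{symbol(k)} is evaluated
    per symbol with a first-order IIR filter, which is algebraically identical
    to the sequential update.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    min_len = (cfg.W - 1) * cfg.xi + 1
    if x.size < min_len:
        raise ValueError(f"input too short: need at least {min_len} samples")

    symbols = _symbol_sequence(x, cfg)
    n = symbols.size
    alpha = cfg.alpha
    n_symbols = math.factorial(cfg.W)

    # total mass sum(F) after update k is a pure geometric series
    total = lfilter([1.0], [1.0, -alpha], np.ones(n))

    # accumulate sum_n F_n ln F_n in symbol chunks to bound memory
    f_logf = np.zeros(n)
    chunk = 24
    for s0 in range(0, n_symbols, chunk):
        s1 = min(s0 + chunk, n_symbols)
        ind = (symbols[:, None] == np.arange(s0, s1)[None, :]).astype(float)
        F = lfilter([1.0], [1.0, -alpha], ind, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(F > 0, F * np.log(F), 0.0)
        f_logf += contrib.sum(axis=1)

    # -sum p ln p = ln(total) - (1/total) * sum F ln F
    S = (np.log(total) - f_logf / total) / math.log(n_symbols)
    S = np.clip(S, 0.0, 1.0)

    burn_samples = int(round(cfg.burn_in * cfg.f))
    mask = np.zeros(n, dtype=bool)
    mask[:burn_samples] = True
    return EntropyTimecourse(S=S, sampling_rate=cfg.f, burn_in_mask=mask, config=cfg)


def _window_slice(onset: float, window: tuple[float, float], f: float, n: int):
    i0 = int(round((onset + window[0]) * f))
    i1 = int(round((onset + window[1]) * f))
    if i0 < 0 or i1 > n:
        return None
    return slice(i0, i1)


def trial_average_entropy(
    S: EntropyTimecourse,
    paradigm: ParadigmSpec,
    window: tuple[float, float] | None = None,
    baseline_windows: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Trial-averaged, baseline-referenced entropy deflection.

    Averages S over all (non-excluded) trial windows and subtracts the mean
    entropy over the rest windows.  Returns the averaged timecourse, one
    sample per entropy sample in the trial window.
    """
    if window is None:
        window = paradigm.trial_window
    if baseline_windows is None:
        baseline_windows = paradigm.rest_windows

    f = S.sampling_rate
    n = S.S.size
    usable = ~S.burn_in_mask

    trials = []
    for onset in paradigm.included_trial_onsets:
        sl = _window_slice(onset, window, f, n)
        if sl is None or not usable[sl].all():
            continue
        trials.append(S.S[sl])
    if not trials:
        raise ValueError("no complete trials inside the recording")
    # trailing trials may be clipped by the entropy timecourse being shorter
    min_len = min(len(t) for t in trials)
    avg = np.mean([t[:min_len] for t in trials], axis=0)

    base_vals = []
    for bs, be in baseline_windows:
        sl = _window_slice(0.0, (bs, be), f, n)
        if sl is None:
            sl = slice(int(round(bs * f)), min(int(round(be * f)), n))
        seg = S.S[sl][usable[sl]]
        if seg.size:
            base_vals.append(seg)
    if not base_vals:
        raise ValueError("no baseline samples available")
    baseline = float(np.concatenate(base_vals).mean())
    return avg - baseline
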