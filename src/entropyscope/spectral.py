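"""Band-limited Hilbert-envelope spectrograms and entropy-oscillation coupling.

A regional broadband signal is filtered into 33 overlapping bands spanning
1-150 Hz; the analytic-signal magnitude per band gives a time-frequency
spectrogram of oscillatory amplitude.  Two couplings with the entropy
timecourse are computed: the per-band Pearson correlation (on unaveraged
data), and a general linear model s = Gβ + ε in which the entropy signal is
regressed on all band envelopes jointly (design orthogonalised via SVD of
G·Gᵀ), yielding the fraction of entropy variance that oscillatory amplitude
explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import fftconvolve, firwin, hilbert

from .paradigms import ParadigmSpec
from .rve import EntropyTimecourse

__all__ = [
    "BandSet",
    "Spectrogram",
    "GlmResult",
    "default_bands",
    "hilbert_spectrogram",
    "trial_average_spectrogram",
    "entropy_envelope_correlation",
    "glm_variance_explained",
]


@dataclass
class BandSet:
    """Ordered list of (low, high) band edges in Hz."""

    bands: list[tuple[float, float]]

    def __post_init__(self) -> None:
        centres = [0.5 * (lo + hi) for lo, hi in self.bands]
        if centres != sorted(centres):
            raise ValueError("bands must be ordered by centre frequency")

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def centres(self) -> np.ndarray:
        return np.array([0.5 * (lo + hi) for lo, hi in self.bands])


def default_bands(n_bands: int = 33, f_min: float = 1.0,
                  f_max: float = 150.0) -> BandSet:
    """33 overlapping bands spanning 1-150 Hz.

    Centres are log-spaced from 1.5 to 140 Hz with bandwidth
    max(2 Hz, 0.5 x centre), giving >= 50% overlap between neighbours; edges
    are clipped to [f_min, f_max].
    """
    c_max = min(140.0, f_max / 1.07)  # keep the top band inside [f_min, f_max]
    centres = np.geomspace(1.5, c_max, n_bands)
    bands = []
    for c in centres:
        bw = max(2.0, 0.5 * c)
        bands.append((max(f_min, c - bw / 2), min(f_max, c + bw / 2)))
    return BandSet(bands)


@dataclass
class Spectrogram:
    """Bands x time envelope amplitudes."""

    envelopes: np.ndarray   # (n_bands, n_samples)
    bands: BandSet
    sampling_rate: float
    edge_mask: np.ndarray | None = None  # True where filter edge effects live
    baseline_relative: bool = False
    trial_averaged: bool = False


@dataclass
class GlmResult:
    beta: np.ndarray
    residual: np.ndarray
    r2: float
    design: np.ndarray   # orthogonalised design, time x components
    n_regressors: int


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> tuple[np.ndarray, int]:
    """Zero-phase FIR band-pass; returns (filtered, edge length in samples).

    The (symmetric, linear-phase) kernel is applied by a single centred
    convolution, which is exactly zero-phase and O(N log N).
    """
    trans = max(0.1 * lo, 0.5)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps = min(numtaps | 1, (x.size - 1) | 1)  # odd, not longer than the data
    hi = min(hi, 0.49 * fs)
    if hi <= lo:
        raise ValueError(f"band ({lo}, {hi}) above Nyquist at fs={fs}")
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return fftconvolve(x, taps, mode="same"), numtaps


def hilbert_spectrogram(x: np.ndarray, bands: BandSet,
                        sampling_rate: float) -> Spectrogram:
    """Per-band analytic-signal amplitude envelope of a broadband signal."""
    x = np.asarray(x, dtype=float)
    if sampling_rate < 2 * max(hi for _, hi in bands.bands):
        raise ValueError("sampling rate below twice the highest band edge")
    env = np.zeros((len(bands), x.size))
    edge = np.zeros(x.size, dtype=bool)
    max_edge = 0
    nfft = next_fast_len(x.size)
    for i, (lo, hi) in enumerate(bands.bands):
        filtered, n_edge = _bandpass(x, lo, hi, sampling_rate)
        env[i] = np.abs(hilbert(filtered, N=nfft)[: x.size])
        max_edge = max(max_edge, n_edge)
    edge[:max_edge] = True
    edge[-max_edge:] = True
    return Spectrogram(envelopes=env, bands=bands, sampling_rate=sampling_rate,
                       edge_mask=edge)


def trial_average_spectrogram(
    spec: Spectrogram,
    paradigm: ParadigmSpec,
    window: tuple[float, float] | None = None,
    baseline_windows: list[tuple[float, float]] | None = None,
) -> Spectrogram:
    """Trial-averaged, baseline-referenced spectrogram.

    Per band: average over (non-excluded) trial windows, minus the band's
    mean envelope over the rest windows.
    """
    if window is None:
        window = paradigm.trial_window
    if baseline_windows is None:
        baseline_windows = paradigm.rest_windows
    fs = spec.sampling_rate
    n = spec.envelopes.shape[1]
    w_len = int(round((window[1] - window[0]) * fs))

    trials = []
    for onset in paradigm.included_trial_onsets:
        i0 = int(round((onset + window[0]) * fs))
        if i0 < 0 or i0 + w_len > n:
            continue
        trials.append(spec.envelopes[:, i0:i0 + w_len])
    if not trials:
        raise ValueError("no complete trials inside the spectrogram")
    avg = np.mean(trials, axis=0)

    base = []
    for bs, be in baseline_windows:
        i0, i1 = int(round(bs * fs)), min(int(round(be * fs)), n)
        if i1 > i0:
            base.append(spec.envelopes[:, i0:i1])
    if not base:
        raise ValueError("no baseline samples available")
    baseline = np.hstack(base).mean(axis=1, keepdims=True)
    return Spectrogram(envelopes=avg - baseline, bands=spec.bands,
                       sampling_rate=fs, baseline_relative=True,
                       trial_averaged=True)


def _align_envelopes(S: EntropyTimecourse, spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """Resample envelopes onto the entropy time axis; drop burn-in and filter edges."""
    t_env = np.arange(spec.envelopes.shape[1]) / spec.sampling_rate
    t_ent = S.times
    env = np.vstack([np.interp(t_ent, t_env, e) for e in spec.envelopes])
    keep = ~S.burn_in_mask
    if spec.edge_mask is not None:
        edge_on_ent = np.interp(t_ent, t_env, spec.edge_mask.astype(float)) > 0
        keep &= ~edge_on_ent
    return S.S[keep], env[:, keep]


def entropy_envelope_correlation(S: EntropyTimecourse,
                                 spec: Spectrogram) -> np.ndarray:
    """Per-band Pearson correlation between entropy and oscillatory envelope.

    Computed on unaveraged data; bands with constant envelope yield NaN.
    """
    s, env = _align_envelopes(S, spec)
    s_c = s - s.mean()
    s_sd = s_c.std()
    out = np.full(env.shape[0], np.nan)
    for i, e in enumerate(env):
        e_c = e - e.mean()
        denom = s_sd * e_c.std()
        if denom > 0:
            out[i] = float((s_c * e_c).mean() / denom)
    return out


def glm_variance_explained(S: EntropyTimecourse, spec: Spectrogram) -> GlmResult:
    """Regress the entropy timecourse on all band envelopes jointly.

    The design matrix of envelopes is orthogonalised through the SVD of its
    covariance G·Gᵀ (i.e. projected onto the principal directions), null
    directions are dropped, and r² = 1 - var(ε)/var(s) reports the fraction
    of entropy variance the oscillatory amplitudes explain.
    """
    s, env = _align_envelopes(S, spec)
    n_bands, n_time = env.shape
    if n_time <= n_bands:
        raise ValueError("need more time points than bands")
    G = env - env.mean(axis=1, keepdims=True)  # bands x time
    # SVD of the covariance GG^T; project the design onto principal directions
    U, vals, _ = np.linalg.svd(G @ G.T)
    keep = vals > vals[0] * 1e-10 if vals[0] > 0 else np.zeros(len(vals), bool)
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} null design directions",
                      stacklevel=2)
    basis = U[:, keep]                 # bands x k
    design = (basis.T @ G).T           # time x k, mutually orthogonal columns
    s_c = s - s.mean()
    beta, *_ = np.linalg.lstsq(design, s_c, rcond=None)
    resid = s_c - design @ beta
    var_s = float(np.var(s_c))
    r2 = 1.0 - float(np.var(resid)) / var_s if var_s > 0 else 0.0
    return GlmResult(beta=beta, residual=resid, r2=float(np.clip(r2, 0.0, 1.0)),
                     design=design, n_regressors=int(keep.sum()))
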