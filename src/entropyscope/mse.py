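"""Sample entropy and multi-scale sample entropy (MSE).

SampEn(m, r) is -ln(A/B) where B counts template pairs whose first m points
match within Chebyshev tolerance r and A counts those that still match over
m+1 points (self-matches excluded).  MSE evaluates SampEn on progressively
coarse-grained versions of the series: scale s replaces the series by means
of non-overlapping blocks of s points, so larger scales probe slower
dynamics.  Defaults follow common electrophysiological practice: m = 2,
r = 20% of the analysed timecourse's standard deviation, recomputed for each
coarse-grained (and each per-trial) segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .paradigms import ParadigmSpec

__all__ = [
    "SampEnConfig",
    "MseCurve",
    "sample_entropy",
    "coarse_grain",
    "mse_curve",
    "task_mse_change",
]


@dataclass(frozen=True)
class SampEnConfig:
    """m: template length; r_frac: tolerance as a fraction of SD.

    r_mode controls the multi-scale tolerance convention: "per_scale"
    recomputes r from each coarse-grained series' own SD (making SampEn
    scale-invariant in distribution for white noise), "global" fixes r from
    the original series (the classic convention, under which white-noise
    SampEn decays with scale).  This is a known sensitivity knob of MSE.
    """

    m: int = 2
    r_frac: float = 0.20
    r_mode: str = "per_scale"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be positive")
        if self.r_mode not in ("per_scale", "global"):
            raise ValueError("r_mode must be 'per_scale' or 'global'")


@dataclass
class MseCurve:
    scales: np.ndarray            # 1..s_max
    sampen_per_scale: np.ndarray  # NaN where undefined
    n_effective: np.ndarray       # floor(N/s) samples per scale


def sample_entropy(x: np.ndarray, cfg: SampEnConfig = SampEnConfig(),
                   r_value: float | None = None) -> float:
    """SampEn = -ln(A/B) with Chebyshev distance and SD-relative tolerance.

    ``r_value`` overrides the SD-relative tolerance with an absolute one
    (used by the "global" multi-scale convention).  Returns ``inf`` when no
    m+1 matches exist (flagged undefined-high) and raises on zero-variance
    input, where the tolerance is degenerate.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < cfg.m + 2:
        raise ValueError(f"need at least m+2={cfg.m + 2} samples, got {N}")
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("zero-variance input: tolerance r is undefined")
    r = cfg.r_frac * sd if r_value is None else float(r_value)

    m = cfg.m
    # templates of length m+1; pairs matching over the first m points (Chebyshev
    # distance <= r) give B, those still matching at point m+1 give A (standard
    # counting where both use the same N-m template set).  A template pair
    # (i, j) matches over k points iff the single-sample match matrix
    # a[i, j] = (|x_i - x_j| <= r) is true on the k diagonal shifts, so the
    # counts come from ANDing shifted views of one boolean matrix.  Rows are
    # processed in chunks to bound memory for long inputs.
    n_t = N - m
    B = 0  # ordered pairs incl. self-matches; corrected below
    A = 0
    chunk = max(64, int(2e7 // N))
    for i0 in range(0, n_t, chunk):
        i1 = min(i0 + chunk, n_t)
        rows = slice(i0, i1 + m)
        a = np.abs(x[rows, None] - x[None, :]) <= r  # (chunk+m, N) booleans
        match = a[: i1 - i0, :n_t]
        for k in range(1, m):
            match = match & a[k: i1 - i0 + k, k: n_t + k]
        B += int(match.sum())
        A += int((match & a[m: i1 - i0 + m, m: n_t + m]).sum())
    B = (B - n_t) // 2  # remove self-matches, count unordered pairs once
    A = (A - n_t) // 2
    if A == 0 or B == 0:
        return np.inf
    return float(-np.log(A / B))


def coarse_grain(x: np.ndarray, s: int) -> np.ndarray:
    """Means of non-overlapping blocks of s points; length floor(N/s)."""
    x = np.asarray(x, dtype=float)
    if s < 1:
        raise ValueError("scale must be >= 1")
    if s > x.size:
        raise ValueError(f"scale {s} exceeds series length {x.size}")
    if s == 1:
        return x.copy()
    n_blocks = x.size // s
    return x[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)


def mse_curve(x: np.ndarray, cfg: SampEnConfig = SampEnConfig(),
              s_max: int = 20) -> MseCurve:
    """SampEn of the coarse-grained series at scales 1..s_max.

    Under the default "per_scale" convention the tolerance r is recomputed
    from each scale's own SD; under "global" it is fixed from the original
    series.  Scales where SampEn is undefined (too short, zero variance, no
    matches) are recorded as NaN with a warning rather than aborting the
    curve.
    """
    x = np.asarray(x, dtype=float)
    r_fixed = cfg.r_frac * float(np.std(x)) if cfg.r_mode == "global" else None
    scales = np.arange(1, s_max + 1)
    vals = np.full(s_max, np.nan)
    n_eff = np.zeros(s_max, dtype=int)
    for i, s in enumerate(scales):
        n_eff[i] = x.size // s
        try:
            cg = coarse_grain(x, int(s))
            v = sample_entropy(cg, cfg, r_value=r_fixed)
            vals[i] = v if np.isfinite(v) else np.nan
        except ValueError as err:
            warnings.warn(f"scale {s}: {err}", stacklevel=2)
    return MseCurve(scales=scales, sampen_per_scale=vals, n_effective=n_eff)


def _segment(x: np.ndarray, f: float, start: float, end: float) -> np.ndarray:
    i0, i1 = int(round(start * f)), int(round(end * f))
    return x[max(i0, 0): min(i1, x.size)]


def task_mse_change(
    x: np.ndarray,
    paradigm: ParadigmSpec,
    cfg: SampEnConfig = SampEnConfig(),
    s_max: int = 20,
    sampling_rate: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-scale task-minus-rest SampEn change on a broadband timecourse.

    SampEn is computed per trial window and averaged over trials, then the
    SampEn of the concatenated rest segments (per scale) is subtracted.
    For the RM task the trials are split into relevant and irrelevant sets;
    target trials are excluded throughout.  Returns a dict mapping condition
    name ("task" for Sternberg; "relevant"/"irrelevant" for RM) to a per-scale
    change array (NaN where undefined).
    """
    f = sampling_rate or paradigm.sampling_rate
    x = np.asarray(x, dtype=float)
    w0, w1 = paradigm.trial_window

    if paradigm.task_name == "rm":
        groups: dict[str, list[float]] = {"relevant": [], "irrelevant": []}
        for e in paradigm.events:
            if e.excluded or e.label not in groups:
                continue
            groups[e.label].append(e.onset)
    else:
        groups = {"task": list(paradigm.included_trial_onsets)}

    # rest reference: SampEn is length-biased, so the rest windows are cut
    # into segments matched to the trial-window length and averaged, exactly
    # as the trials are
    seg_len = int(round((w1 - w0) * f))
    rest_curves = []
    for bs, be in paradigm.rest_windows:
        seg = _segment(x, f, bs, be)
        for j in range(seg.size // seg_len):
            rest_curves.append(
                mse_curve(seg[j * seg_len:(j + 1) * seg_len], cfg, s_max).sampen_per_scale
            )
    if not rest_curves:
        raise ValueError("rest windows shorter than the trial window")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rest_curve = np.nanmean(np.vstack(rest_curves), axis=0)

    out: dict[str, np.ndarray] = {}
    for name, onsets in groups.items():
        per_trial = []
        for onset in onsets:
            seg = _segment(x, f, onset + w0, onset + w1)
            if seg.size < int(round((w1 - w0) * f)):
                continue  # clipped trial at the recording edge
            per_trial.append(mse_curve(seg, cfg, s_max).sampen_per_scale)
        if not per_trial:
            raise ValueError(f"no complete trials for condition {name!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            task_curve = np.nanmean(np.vstack(per_trial), axis=0)
        out[name] = task_curve - rest_curve
    return out
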