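"""Temporal ICA parcellation of voxel-wise entropy timecourses.

Entropy timecourses are down-sampled to 1 s resolution, concatenated across
subjects and tasks into a voxels x time matrix Λ, whitened by PCA (default
45 dimensions) and decomposed by temporal ICA (default 40 components) as
Λ = A·S: rows of S are temporally independent entropy signals and columns of
A are their spatial maps.  Thresholded columns of A then serve as weights to
reconstruct regional broadband timecourses from the full-rate beamformed
voxel data, on which regional entropy and spectrograms are recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .beamforming import SourceVolume
from .paradigms import ParadigmSpec
from .rve import EntropyTimecourse

__all__ = [
    "EntropyDataset",
    "DecompositionResult",
    "RegionalTimecourse",
    "downsample_entropy",
    "build_dataset",
    "decompose",
    "select_components",
    "reconstruct_region",
]


@dataclass
class EntropyDataset:
    """Concatenated voxels x time matrix of 1 s entropy with segment bookkeeping."""

    Lam: np.ndarray                       # (n_voxels, total_time)
    segment_boundaries: list[tuple[int, int]]  # per-subject column ranges
    voxel_index: np.ndarray | None = None      # map rows -> grid voxels

    def subject_matrix(self, i: int) -> np.ndarray:
        a, b = self.segment_boundaries[i]
        return self.Lam[:, a:b]


@dataclass
class DecompositionResult:
    A: np.ndarray          # mixing matrix, voxels x components
    S_ic: np.ndarray       # independent signals, components x time
    n_pca: int
    n_ica: int
    mean: np.ndarray       # per-voxel mean removed before whitening
    retained: list[int] = field(default_factory=list)
    variance_explained: float = 0.0  # fraction of Λ variance captured by the model


@dataclass
class RegionalTimecourse:
    label: str
    weights: np.ndarray      # per-voxel, zero outside threshold, sum|w| = 1
    timecourse: np.ndarray   # full-rate broadband regional signal
    sampling_rate: float


def downsample_entropy(S: EntropyTimecourse, dt: float = 1.0) -> np.ndarray:
    """Non-overlapping block means of the entropy timecourse at resolution dt.

    Burn-in samples are excluded from the means; blocks that are entirely
    burn-in repeat the first valid block's value so the output grid is regular.
    """
    block = int(round(dt * S.sampling_rate))
    if S.S.size < block:
        raise ValueError("timecourse shorter than one down-sampling block")
    n_blocks = S.S.size // block
    out = np.empty(n_blocks)
    valid = ~S.burn_in_mask
    for j in range(n_blocks):
        sl = slice(j * block, (j + 1) * block)
        seg = S.S[sl][valid[sl]]
        out[j] = seg.mean() if seg.size else np.nan
    if np.isnan(out).any():
        first = out[~np.isnan(out)][0]
        out = np.where(np.isnan(out), first, out)
    return out


def build_dataset(
    per_subject: list[np.ndarray],
    mask: np.ndarray | None = None,
    demean: bool = True,
) -> EntropyDataset:
    """Concatenate per-subject (voxels x time) entropy matrices along time.

    All subjects must share the common voxel grid.  Within-subject per-voxel
    means are removed so the ICA sees fluctuations, not subject offsets.
    """
    n_vox = per_subject[0].shape[0]
    for m in per_subject:
        if m.shape[0] != n_vox:
            raise ValueError("all subjects must share the common voxel grid")
    mats = []
    boundaries = []
    col = 0
    for m in per_subject:
        m = np.asarray(m, dtype=float)
        if mask is not None:
            m = m[mask]
        if demean:
            m = m - m.mean(axis=1, keepdims=True)
        mats.append(m)
        boundaries.append((col, col + m.shape[1]))
        col += m.shape[1]
    idx = np.flatnonzero(mask) if mask is not None else None
    return EntropyDataset(Lam=np.hstack(mats), segment_boundaries=boundaries,
                          voxel_index=idx)


def decompose(
    dataset: EntropyDataset,
    n_pca: int = 45,
    n_ica: int = 40,
    seed: int = 0,
    max_retries: int = 3,
) -> DecompositionResult:
    """PCA-whiten Λ to n_pca dimensions, then extract n_ica temporally
    independent components (FastICA).

    Component sign is fixed so the largest-magnitude voxel weight of each
    spatial map is positive, and columns of A are unit-norm, resolving the
    usual ICA ambiguities.  Deterministic under ``seed``.
    """
    Lam = dataset.Lam
    n_vox, n_time = Lam.shape
    if n_time < n_pca:
        raise ValueError(f"need at least n_pca={n_pca} time points, got {n_time}")
    if n_ica > n_pca:
        raise ValueError("n_ica cannot exceed n_pca")

    mean = Lam.mean(axis=1)
    X = (Lam - mean[:, None]).T  # time x voxels; temporal ICA: time = samples

    pca = PCA(n_components=n_pca, svd_solver="auto", random_state=seed)
    X_red = pca.fit_transform(X)  # time x n_pca

    last_err: Exception | None = None
    for attempt in range(max_retries):
        ica = FastICA(n_components=n_ica, whiten="unit-variance",
                      random_state=seed + attempt, max_iter=2000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("error", UserWarning)  # non-convergence warning
            try:
                S_t = ica.fit_transform(X_red)  # time x n_ica
            except UserWarning as err:
                last_err = err
                continue
        break
    else:
        raise RuntimeError(f"ICA failed to converge after {max_retries} seeds: {last_err}")

    # back-project the ICA mixing through the PCA loadings to voxel space
    A = pca.components_.T @ ica.mixing_  # voxels x n_ica
    S = S_t.T                            # n_ica x time

    # sign convention: largest-|weight| voxel positive; scale: unit-norm columns
    for c in range(n_ica):
        peak = np.argmax(np.abs(A[:, c]))
        if A[peak, c] < 0:
            A[:, c] *= -1
            S[c] *= -1
        norm = np.linalg.norm(A[:, c])
        if norm > 0:
            A[:, c] /= norm
            S[c] *= norm

    recon = A @ S
    total = float(np.sum((Lam - mean[:, None]) ** 2))
    ve = 1.0 - float(np.sum((Lam - mean[:, None] - recon) ** 2)) / total if total > 0 else 0.0
    return DecompositionResult(A=A, S_ic=S, n_pca=n_pca, n_ica=n_ica,
                               mean=mean, variance_explained=ve)


def _trial_modulation_score(signal: np.ndarray, onsets_idx: np.ndarray,
                            win: int, rng: np.random.Generator,
                            n_surrogates: int = 100) -> float:
    """Variance of the trial average divided by that of trial-shuffled surrogates."""
    n = signal.size
    valid = onsets_idx[(onsets_idx >= 0) & (onsets_idx + win <= n)]
    if valid.size < 2:
        return 1.0
    trials = np.stack([signal[i:i + win] for i in valid])
    obs = float(np.var(trials.mean(axis=0)))
    surro = np.empty(n_surrogates)
    for s in range(n_surrogates):
        fake = rng.integers(0, n - win, size=valid.size)
        surro[s] = np.var(np.stack([signal[i:i + win] for i in fake]).mean(axis=0))
    denom = float(surro.mean())
    return obs / denom if denom > 0 else 1.0


def select_components(
    result: DecompositionResult,
    paradigm: ParadigmSpec | None = None,
    dataset: EntropyDataset | None = None,
    top_k: int | None = None,
    threshold: float | None = 2.0,
    override: list[int] | None = None,
    dt: float = 1.0,
    seed: int = 0,
) -> list[int]:
    """Select components of interest, replacing visual inspection.

    Components are ranked by a task-modulation ratio — variance of the
    trial-averaged component signal over the mean variance of trial-shuffled
    surrogates (noise components score about 1) — and those above ``threshold``
    (or the ``top_k`` best) are retained.  A manual ``override`` list wins
    outright.  The retained set is stored on the result and returned.
    """
    n_ica = result.S_ic.shape[0]
    if override is not None:
        result.retained = sorted(set(override))
        return result.retained
    if paradigm is None:
        result.retained = list(range(n_ica))
        return result.retained

    rng = np.random.default_rng(seed)
    onsets = np.array([int(round(t / dt)) for t in paradigm.included_trial_onsets])
    win = max(1, int(round((paradigm.trial_window[1] - paradigm.trial_window[0]) / dt)))
    scores = np.array([
        _trial_modulation_score(result.S_ic[c], onsets, win, rng)
        for c in range(n_ica)
    ])
    if top_k is not None:
        retained = list(np.argsort(scores)[::-1][:top_k])
    else:
        retained = list(np.flatnonzero(scores >= (threshold or 2.0)))
    if not retained:
        warnings.warn("no components passed selection; retaining all", stacklevel=2)
        retained = list(range(n_ica))
    result.retained = sorted(int(i) for i in retained)
    return result.retained


def reconstruct_region(
    volume: SourceVolume,
    mixing_column: np.ndarray,
    threshold: float | str = "2sd",
    label: str = "region",
) -> RegionalTimecourse:
    """Weighted sum of full-rate voxel timecourses from a thresholded map.

    Weights below the threshold (default: |w| < 2 SD of the column) are
    zeroed and the survivors renormalised to sum(|w|) = 1, so the regional
    signal is a convex-style combination of the region's voxels.
    """
    col = np.asarray(mixing_column, dtype=float)
    if col.size != volume.timecourses.shape[0]:
        raise ValueError("mixing column length must match voxel count")
    if threshold == "2sd":
        thr = 2.0 * float(np.std(col))
    else:
        thr = float(threshold)
    w = np.where(np.abs(col) >= thr, col, 0.0)
    total = np.abs(w).sum()
    if total == 0:
        raise ValueError("all weights fall below the threshold")
    w = w / total
    tc = w @ volume.timecourses
    return RegionalTimecourse(label=label, weights=w, timecourse=tc,
                              sampling_rate=volume.sampling_rate)
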