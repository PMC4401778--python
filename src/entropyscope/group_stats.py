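"""Two-group inference on task-induced entropy changes.

Per subject and region, the statistic is the mean entropy over task windows
minus the mean over rest windows.  Groups are compared per region with (a) a
label-permutation test on the difference of group means (default 500,000
iterations, add-one two-sided p) and (b) a two-sided rank-sum test; the
threshold is Bonferroni-corrected across regions (default N = 12) and a
region is declared significant only when BOTH tests pass — a conjunction rule
that guards against distributional assumptions of either test alone.

A paired signed-rank comparison of per-subject trial-averaged-entropy
variance between homologous left/right regions tests hemispheric
lateralisation of the entropy response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .paradigms import ParadigmSpec
from .rve import EntropyTimecourse

__all__ = [
    "GroupComparison",
    "task_entropy_change",
    "permutation_test",
    "ranksum_test",
    "compare_regions",
    "lateralisation_variance_test",
    "mse_group_comparison",
]


@dataclass
class GroupComparison:
    region: str
    observed_diff: float   # mean(group 2) - mean(group 1)
    perm_p: float
    ranksum_p: float
    bonferroni_n: int
    significant: bool


def task_entropy_change(S: EntropyTimecourse, paradigm: ParadigmSpec) -> float:
    """Mean entropy over task windows minus mean over rest windows.

    Task windows are the per-trial averaging windows with excluded (target)
    trials removed; burn-in samples are ignored throughout.
    """
    f = S.sampling_rate
    n = S.S.size
    usable = ~S.burn_in_mask
    w0, w1 = paradigm.trial_window

    task_vals = []
    for onset in paradigm.included_trial_onsets:
        i0, i1 = int(round((onset + w0) * f)), int(round((onset + w1) * f))
        if i0 < 0 or i1 > n:
            continue
        seg = S.S[i0:i1][usable[i0:i1]]
        if seg.size:
            task_vals.append(seg)
    rest_vals = []
    for bs, be in paradigm.rest_windows:
        i0, i1 = int(round(bs * f)), min(int(round(be * f)), n)
        if i1 <= i0:
            continue
        seg = S.S[i0:i1][usable[i0:i1]]
        if seg.size:
            rest_vals.append(seg)
    if not task_vals or not rest_vals:
        raise ValueError("recording lacks usable task or rest windows")
    return float(np.concatenate(task_vals).mean() - np.concatenate(rest_vals).mean())


def permutation_test(group1: np.ndarray, group2: np.ndarray,
                     n_iter: int = 500_000, seed: int = 0) -> float:
    """Two-sided label-permutation p for the difference of group means.

    Random relabellings preserve group sizes ("sham" groups with an equal mix);
    p = (1 + #{|null| >= |obs|}) / (1 + n_iter), so p is never zero.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    n1 = g1.size
    obs = abs(g2.mean() - g1.mean())

    rng = np.random.default_rng(seed)
    total = pooled.sum()
    count = 0
    chunk = max(1, min(n_iter, int(2e7) // pooled.size))
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        # argsort of uniforms = random permutation per row
        perm = np.argsort(rng.random((b, pooled.size)), axis=1)
        sham1 = pooled[perm[:, :n1]].sum(axis=1)
        null = np.abs((total - sham1) / g2.size - sham1 / n1)
        count += int((null >= obs - 1e-15).sum())
        done += b
    return (1 + count) / (1 + n_iter)


def ranksum_test(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small samples without ties, else the
    tie-corrected normal approximation."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if np.all(np.concatenate([g1, g2]) == g1[0]):
        return 1.0
    small = g1.size + g2.size <= 25
    has_ties = len(np.unique(np.concatenate([g1, g2]))) < g1.size + g2.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def compare_regions(
    table: pd.DataFrame,
    bonferroni_n: int = 12,
    n_iter: int = 500_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Per-region two-group comparison with the conjunction decision rule.

    ``table`` needs columns subject, group (1/2), region, delta; rows for the
    same subject x region (e.g. the two tasks) are pooled as independent
    sessions.  A region is significant iff BOTH the permutation p and the
    rank-sum p fall below alpha / bonferroni_n.
    """
    required = {"subject", "group", "region", "delta"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    thresh = alpha / bonferroni_n
    out = []
    for r, (region, sub) in enumerate(table.groupby("region", sort=True)):
        g1 = sub.loc[sub["group"] == 1, "delta"].to_numpy()
        g2 = sub.loc[sub["group"] == 2, "delta"].to_numpy()
        if g1.size < 2 or g2.size < 2:
            raise ValueError(f"region {region}: need >=2 subjects per group")
        p_perm = permutation_test(g1, g2, n_iter=n_iter, seed=seed + r)
        p_rank = ranksum_test(g1, g2)
        out.append(GroupComparison(
            region=str(region),
            observed_diff=float(g2.mean() - g1.mean()),
            perm_p=p_perm,
            ranksum_p=p_rank,
            bonferroni_n=bonferroni_n,
            significant=bool(p_perm < thresh and p_rank < thresh),
        ))
    return out


def lateralisation_variance_test(left_var: np.ndarray,
                                 right_var: np.ndarray) -> float:
    """Paired two-sided signed-rank p comparing per-subject variances of the
    trial-averaged entropy timecourse between hemispheres."""
    lv = np.asarray(left_var, dtype=float)
    rv = np.asarray(right_var, dtype=float)
    if lv.size != rv.size or lv.size < 2:
        raise ValueError("need >= 2 paired subjects")
    diff = lv - rv
    if np.all(diff == 0):
        return 1.0
    res = stats.wilcoxon(lv, rv, alternative="two-sided")
    return float(res.pvalue)


def mse_group_comparison(
    table: pd.DataFrame,
    bonferroni_n: int = 12,
    n_iter: int = 500_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-scale two-group comparison of MSE change, one test per scale.

    ``table`` needs columns subject, group, region, scale, delta; the same
    conjunction machinery as :func:`compare_regions` is applied independently
    at each scale (NaN deltas, e.g. undefined SampEn at long scales, are
    dropped).  Returns a tidy frame of decisions.
    """
    required = {"subject", "group", "region", "scale", "delta"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for s, sub in table.dropna(subset=["delta"]).groupby("scale", sort=True):
        comps = compare_regions(sub, bonferroni_n=bonferroni_n,
                                n_iter=n_iter, seed=seed + 101 * int(s),
                                alpha=alpha)
        for c in comps:
            rows.append({"scale": int(s), "region": c.region,
                         "observed_diff": c.observed_diff,
                         "perm_p": c.perm_p, "ranksum_p": c.ranksum_p,
                         "significant": c.significant})
    return pd.DataFrame(rows)
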