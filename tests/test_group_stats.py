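"""Two-group inference: permutation and rank-sum oracles, conjunction rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

import entropyscope as es


def exhaustive_permutation_p(g1, g2):
    """Enumerate every split of the pooled sample into the two group sizes."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    obs = abs(np.mean(g2) - np.mean(g1))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        total += 1
        if abs(b.mean() - a.mean()) >= obs - 1e-12:
            count += 1
    return count / total


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        p = es.permutation_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]),
                                n_iter=2000, seed=0)
        assert p == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monte_carlo_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = rng.standard_normal(3), rng.standard_normal(3) + 1.0
        exact = exhaustive_permutation_p(g1, g2)
        n_iter = 20_000
        mc = es.permutation_test(g1, g2, n_iter=n_iter, seed=seed)
        se = np.sqrt(exact * (1 - exact) / n_iter)
        assert abs(mc - exact) <= max(3 * se, 2 / n_iter + 1e-9)

    def test_deterministic_under_seed(self, rng):
        g1, g2 = rng.standard_normal(8), rng.standard_normal(8)
        p1 = es.permutation_test(g1, g2, n_iter=5000, seed=99)
        p2 = es.permutation_test(g1, g2, n_iter=5000, seed=99)
        assert p1 == p2

    def test_null_p_values_are_uniform(self):
        """KS test of replicate p-values against U(0,1) under the null."""
        from scipy import stats
        rng = np.random.default_rng(7)
        ps = [es.permutation_test(rng.standard_normal(8), rng.standard_normal(8),
                                  n_iter=400, seed=k) for k in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            es.permutation_test(np.array([1.0]), np.array([2.0]), n_iter=0)
        with pytest.raises(ValueError):
            es.permutation_test(np.array([]), np.array([1.0]), n_iter=10)


class TestRanksum:
    def test_extreme_separation_exact_p(self):
        assert es.ranksum_test(np.array([1.0, 2, 3]),
                               np.array([10.0, 11, 12])) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert es.ranksum_test(np.array([2.0, 2, 2]), np.array([2.0, 2, 2])) == 1.0

    def test_monotone_transform_invariance(self, rng):
        g1, g2 = rng.standard_normal(10), rng.standard_normal(10) + 0.5
        p = es.ranksum_test(g1, g2)
        assert es.ranksum_test(np.exp(g1), np.exp(g2)) == pytest.approx(p)


class TestCompareRegions:
    @staticmethod
    def _table(rng, n=8, regions=4, shift_region=None, shift=0.0):
        rows = []
        for r in range(regions):
            for g in (1, 2):
                for s in range(n):
                    delta = rng.standard_normal() * 0.1
                    if g == 2 and r == shift_region:
                        delta += shift
                    rows.append({"subject": s + (g - 1) * n, "group": g,
                                 "region": f"reg{r}", "delta": delta})
        return pd.DataFrame(rows)

    def test_planted_effect_flagged_alone(self, rng):
        tab = self._table(rng, n=10, regions=4, shift_region=2, shift=1.0)
        comps = es.compare_regions(tab, bonferroni_n=4, n_iter=5000, seed=0)
        assert [c.region for c in comps if c.significant] == ["reg2"]

    def test_conjunction_monotone(self, rng):
        tab = self._table(rng, n=10, regions=3, shift_region=0, shift=0.6)
        for c in es.compare_regions(tab, bonferroni_n=3, n_iter=5000, seed=1):
            if c.significant:
                assert c.perm_p < 0.05 / 3 and c.ranksum_p < 0.05 / 3

    def test_bonferroni_one_is_uncorrected(self, rng):
        tab = self._table(rng, n=10, regions=1, shift_region=0, shift=0.25)
        c12 = es.compare_regions(tab, bonferroni_n=12, n_iter=5000, seed=2)[0]
        c1 = es.compare_regions(tab, bonferroni_n=1, n_iter=5000, seed=2)[0]
        assert c1.perm_p == c12.perm_p
        if c12.significant:
            assert c1.significant

    def test_familywise_error_controlled(self):
        """Over 200 null cohorts of 12 regions, the conjunction-with-Bonferroni
        family-wise error stays within 0.05 + 2 binomial SEs."""
        rng = np.random.default_rng(2024)
        n_cohorts, fwe_hits = 200, 0
        for k in range(n_cohorts):
            tab = self._table(rng, n=11, regions=12)
            comps = es.compare_regions(tab, bonferroni_n=12, n_iter=2000, seed=k)
            fwe_hits += any(c.significant for c in comps)
        fwe = fwe_hits / n_cohorts
        assert fwe <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_cohorts)

    def test_null_rejection_rate_near_nominal(self):
        """Uncorrected single-region permutation rejections occur at ~alpha."""
        rng = np.random.default_rng(77)
        rejections = sum(
            es.permutation_test(rng.standard_normal(8), rng.standard_normal(8),
                                n_iter=1000, seed=k) < 0.05
            for k in range(300)
        )
        rate = rejections / 300
        assert rate == pytest.approx(0.05, abs=2.5 * np.sqrt(0.05 * 0.95 / 300))


class TestLateralisation:
    def test_identical_hemispheres(self):
        v = np.array([0.2, 0.3, 0.25, 0.22])
        assert es.lateralisation_variance_test(v, v) == 1.0

    def test_reduced_right_variance_detected(self):
        rng = np.random.default_rng(0)
        left = 0.04 + 0.01 * rng.random(11)
        right = 0.25 * left * (1 + 0.05 * rng.standard_normal(11))
        assert es.lateralisation_variance_test(left, right) < 0.05

    def test_sign_flip_preserves_p(self, rng):
        left = rng.random(9) + 0.5
        right = rng.random(9) + 0.3
        assert es.lateralisation_variance_test(left, right) == pytest.approx(
            es.lateralisation_variance_test(right, left))


class TestMseGroupComparison:
    @staticmethod
    def _mse_table(rng, n=10, scales=5, effect_scales=(), shift=1.0):
        rows = []
        for sc in range(1, scales + 1):
            for r in range(3):
                for g in (1, 2):
                    for s in range(n):
                        d = rng.standard_normal() * 0.1
                        if g == 2 and r == 0 and sc in effect_scales:
                            d += shift
                        rows.append({"subject": s + (g - 1) * n, "group": g,
                                     "region": f"reg{r}", "scale": sc, "delta": d})
        return pd.DataFrame(rows)

    def test_effect_confined_to_planted_scales(self, rng):
        tab = self._mse_table(rng, effect_scales=(1, 2))
        out = es.mse_group_comparison(tab, bonferroni_n=12, n_iter=5000, seed=0)
        sig = out[out.significant]
        assert set(sig.scale) == {1, 2}
        assert set(sig.region) == {"reg0"}

    def test_null_table_mostly_clean(self, rng):
        tab = self._mse_table(rng, effect_scales=())
        out = es.mse_group_comparison(tab, bonferroni_n=12, n_iter=5000, seed=1)
        assert not out.significant.any()

    def test_scale1_equals_plain_comparison(self, rng):
        tab = self._mse_table(rng, scales=3, effect_scales=(1,))
        out = es.mse_group_comparison(tab, bonferroni_n=3, n_iter=4000, seed=5)
        s1 = out[out.scale == 1].set_index("region")
        plain = es.compare_regions(tab[tab.scale == 1], bonferroni_n=3,
                                   n_iter=4000, seed=5 + 101)
        for c in plain:
            assert s1.loc[c.region, "perm_p"] == pytest.approx(c.perm_p)
            assert s1.loc[c.region, "ranksum_p"] == pytest.approx(c.ranksum_p)


class TestTaskEntropyChange:
    def test_constructed_step_change(self, sternberg):
        fs = sternberg.sampling_rate
        n = int(sternberg.total_duration * fs)
        S = np.full(n, 0.5)
        w0, w1 = sternberg.trial_window
        for onset in sternberg.trial_onsets:
            S[int((onset + w0) * fs): int((onset + w1) * fs)] += 0.1
        tc = es.EntropyTimecourse(S=S, sampling_rate=fs,
                                  burn_in_mask=np.zeros(n, bool),
                                  config=es.RveConfig(f=fs))
        assert es.task_entropy_change(tc, sternberg) == pytest.approx(0.1, abs=1e-9)
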