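"""Lomb-Scargle periodograms, Pearson correlation, quartile ANOVA/Tukey."""

import numpy as np
import pytest
from scipy import signal, stats

from photofoot import (PositionProfile, lomb_scargle, pearson,
                       quartile_analysis)
from photofoot.photogeometry import DipyrimidineStep


def profile(offsets, values, measure="cpd_enrichment", symmetrized=False):
    return PositionProfile(measure=measure, offsets=np.asarray(offsets, float),
                           values=np.asarray(values, float),
                           symmetrized=symmetrized)


class TestLombScargle:
    def test_pure_cosine_peak_at_10bp(self):
        t = np.arange(-73, 74)
        y = np.cos(2 * np.pi * t / 10.0)
        pg = lomb_scargle(profile(t, y), n_permutations=0)
        assert pg.peak_period == pytest.approx(10.0, abs=0.01)
        assert pg.snr > 10

    def test_constant_profile_null_case(self):
        pg = lomb_scargle(profile(np.arange(20), np.ones(20)),
                          n_permutations=100)
        assert pg.p_value == 1.0
        assert pg.peak_period is None
        assert np.all(pg.power == 0)

    def test_matches_scipy_lombscargle(self):
        # independent cross-check of the spectral estimator itself
        rng = np.random.default_rng(71)
        t = np.arange(-73, 74, dtype=float)
        y = np.cos(2 * np.pi * t / 10.3) + rng.normal(0, 0.5, t.size)
        pg = lomb_scargle(profile(t, y), grid_step=0.05, n_permutations=0)
        yc = y - y.mean()
        freqs = 2 * np.pi / pg.periods
        ref = signal.lombscargle(t, yc, freqs)
        ref = ref / yc.var(ddof=1)  # scipy returns (A^2 n/4)-scaled power
        r = stats.pearsonr(pg.power, ref)[0]
        assert r > 0.9999
        assert pg.periods[np.argmax(ref)] == pytest.approx(pg.peak_period,
                                                           abs=0.05)

    def test_noisy_cosine_recovery_across_seeds(self):
        t = np.arange(-73, 74, dtype=float)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.cos(2 * np.pi * t / 10.2) + rng.normal(0, 1.0, t.size)
            pg = lomb_scargle(profile(t, y), grid_step=0.02,
                              n_permutations=199, seed=seed)
            if abs(pg.peak_period - 10.2) <= 0.2 and pg.p_value < 0.01:
                hits += 1
        assert hits >= 9

    def test_peak_invariant_to_offset_and_scale(self):
        t = np.arange(-50, 51, dtype=float)
        rng = np.random.default_rng(73)
        y = np.cos(2 * np.pi * t / 9.7) + rng.normal(0, 0.3, t.size)
        pg1 = lomb_scargle(profile(t, y), n_permutations=0)
        pg2 = lomb_scargle(profile(t, 100.0 + 5.0 * y), n_permutations=0)
        assert pg1.peak_period == pg2.peak_period
        np.testing.assert_allclose(pg1.power, pg2.power, atol=1e-8)

    def test_permutation_p_reproducible_under_seed(self):
        t = np.arange(-30, 31, dtype=float)
        rng = np.random.default_rng(79)
        y = rng.normal(size=t.size)
        p1 = lomb_scargle(profile(t, y), grid_step=0.1, n_permutations=300,
                          seed=5).p_value
        p2 = lomb_scargle(profile(t, y), grid_step=0.1, n_permutations=300,
                          seed=5).p_value
        assert p1 == p2

    def test_permutation_p_uniform_on_noise(self):
        # KS test over seeded pure-noise profiles
        t = np.arange(-40, 41, dtype=float)
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            y = rng.normal(size=t.size)
            pg = lomb_scargle(profile(t, y), grid_step=0.1,
                              n_permutations=99, seed=seed)
            pvals.append(pg.p_value)
        d, p_ks = stats.kstest(pvals, "uniform")
        assert p_ks > 0.01

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle(profile(np.arange(5), np.arange(5.0)))


class TestPearson:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(83)
        p = profile(np.arange(20), rng.normal(size=20))
        res = pearson(p, p)
        assert res.r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(89)
        p = profile(np.arange(20), rng.normal(size=20))
        q = profile(np.arange(20), -p.values)
        assert pearson(p, q).r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(97)
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        res = pearson(profile(np.arange(20), x), profile(np.arange(20), y))
        # brute-force covariance formula
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        tstat = r_oracle * np.sqrt(18 / (1 - r_oracle ** 2))
        p_oracle = 2 * stats.t.sf(abs(tstat), 18)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert res.n == 20

    def test_only_shared_offsets_used(self):
        p = profile(np.arange(10), np.arange(10.0))
        q = profile(np.arange(5, 15), np.arange(5, 15, dtype=float) ** 2)
        assert pearson(p, q).n == 5

    def test_zero_variance_rejected(self):
        p = profile(np.arange(5), np.ones(5))
        q = profile(np.arange(5), np.arange(5.0))
        with pytest.raises(ValueError):
            pearson(p, q)


def make_steps(distances, torsions, half_positions):
    return [
        DipyrimidineStep(structure_id="s", chain_id="A", pos5=i, pos3=i + 1,
                         bases="TT", distance=float(d), torsion=float(t),
                         half_pos=float(h))
        for i, (d, t, h) in enumerate(zip(distances, torsions, half_positions))
    ]


class TestQuartileAnalysis:
    def test_interpolated_percentile_cuts(self):
        vals = np.arange(1.0, 9.0)   # {1..8}
        assert np.percentile(vals, 25) == pytest.approx(2.75)
        assert np.percentile(vals, 75) == pytest.approx(6.25)
        steps = make_steps(vals, vals, np.arange(8) + 0.5)
        e = profile(np.arange(8) + 0.5, np.ones(8))
        table = quartile_analysis(steps, e)
        assert table.thresholds["distance"] == (pytest.approx(2.75),
                                                pytest.approx(6.25))
        # low = {1,2}, high = {7,8}
        assert len(table.categories["low_low"]) == 2
        assert len(table.categories["high_high"]) == 2

    def test_identical_groups_null_anova(self):
        rng = np.random.default_rng(101)
        n = 40
        d = rng.permutation(np.arange(n, dtype=float))
        t = rng.permutation(np.arange(n, dtype=float))
        e = profile(np.arange(n) + 0.5, np.full(n, 2.0))
        table = quartile_analysis(make_steps(d, t, np.arange(n) + 0.5), e)
        assert table.anova_f == 0.0
        assert table.anova_p == 1.0
        assert all(p == pytest.approx(1.0) for p in table.tukey.values())

    def test_anova_and_tukey_match_independent_oracle(self):
        # three seeded groups with known means, checked against
        # scipy.stats.f_oneway / tukey_hsd computed directly on the groups
        rng = np.random.default_rng(103)
        n = 300
        d = rng.uniform(3.5, 5.5, n)
        t = rng.uniform(25, 50, n)
        h = np.arange(n) + 0.5
        e_vals = 2.0 - 0.1 * stats.zscore(d) - 0.1 * stats.zscore(t) \
            + rng.normal(0, 0.05, n)
        e = profile(h, e_vals)
        steps = make_steps(d, t, h)
        table = quartile_analysis(steps, e)

        groups = [v for v in table.categories.values() if len(v) > 0]
        f_ref, p_ref = stats.f_oneway(*groups)
        assert table.anova_f == pytest.approx(f_ref, rel=1e-9)
        assert table.anova_p == pytest.approx(p_ref, rel=1e-9)

        nonempty = {k: v for k, v in table.categories.items() if len(v) > 0}
        keys = sorted(nonempty)
        ref = stats.tukey_hsd(*[nonempty[k] for k in keys])
        for i, a in enumerate(keys):
            for j, b in enumerate(keys):
                if i < j:
                    pair = (a, b) if (a, b) in table.tukey else (b, a)
                    assert table.tukey[pair] == pytest.approx(
                        ref.pvalue[i, j], abs=1e-4)

    def test_monotone_enrichment_orders_groups(self):
        rng = np.random.default_rng(107)
        n = 400
        d = rng.uniform(3.5, 5.5, n)
        t = rng.uniform(25, 50, n)
        h = np.arange(n) + 0.5
        e_vals = 1.0 - 0.15 * stats.zscore(d) - 0.15 * stats.zscore(t) \
            + rng.normal(0, 0.05, n)
        table = quartile_analysis(make_steps(d, t, h), profile(h, e_vals))
        means = table.group_means()
        assert means["low_low"] > means["mid_mid"] > means["high_high"]

    def test_symmetrized_profile_joined_on_absolute_offset(self):
        d = np.arange(1.0, 9.0)
        h = -(np.arange(8) + 0.5)     # all steps on the negative arm
        e = profile(np.arange(8) + 0.5, np.arange(8.0) + 1.0, symmetrized=True)
        table = quartile_analysis(make_steps(d, d, h), e)
        assert sum(len(v) for v in table.categories.values()) > 0
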