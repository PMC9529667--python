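"""Lesion assignment, dyad alignment and CPD enrichment normalization."""

import numpy as np
import pytest

from photofoot import (DamageSimSpec, DamageTrack, DyadMap, assign_lesions,
                       dyad_align, enrichment, gen_damage_data)
from photofoot.damage_enrichment import read_damage_track, write_damage_track
from photofoot.nucleosome_frame import PositionProfile


def track(counts, sample="cellular"):
    return DamageTrack(sample=sample, counts=counts)


class TestAssignLesions:
    def test_half_integer_midpoint_rule(self):
        t = assign_lesions(track({("chrI", 100.0, "+"): 1}), "half_integer")
        assert t.counts == {("chrI", 100.5, "+"): 1}

    def test_integer_both_bases(self):
        t = assign_lesions(track({("chrI", 100.0, "+"): 1}), "integer")
        assert t.counts == {("chrI", 100.0, "+"): 1, ("chrI", 101.0, "+"): 1}

    def test_minus_strand_midpoint_toward_lower_coordinate(self):
        t = assign_lesions(track({("chrI", 100.0, "-"): 2}), "half_integer")
        assert t.counts == {("chrI", 99.5, "-"): 2}

    def test_integer_convention_doubles_total(self):
        rng = np.random.default_rng(41)
        counts = {("chrI", float(p), s): int(c)
                  for p, s, c in zip(rng.integers(1, 10_000, 200),
                                     rng.choice(["+", "-"], 200),
                                     rng.integers(0, 20, 200))}
        raw = track(counts)
        half = assign_lesions(raw, "half_integer")
        full = assign_lesions(raw, "integer")
        assert half.total() == raw.total()
        assert full.total() == 2 * raw.total()

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            assign_lesions(track({}), "thirds")


class TestDyadAlign:
    def test_offset_arithmetic(self):
        t = DamageTrack(sample="cellular",
                        counts={("chrI", 1010.0, "+"): 3},
                        convention="integer")
        dyads = DyadMap(entries=[("chrI", 1000, "+")])
        prof = dyad_align(t, dyads, window=73)
        assert prof.value_at(10) == 3.0

    def test_minus_orientation_flips_offset(self):
        t = DamageTrack(sample="cellular",
                        counts={("chrI", 1010.0, "+"): 3},
                        convention="integer")
        dyads = DyadMap(entries=[("chrI", 1000, "-")])
        prof = dyad_align(t, dyads, window=73)
        assert prof.value_at(-10) == 3.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(43)
        positions = rng.choice(np.arange(1, 5000), size=400, replace=False)
        counts = {("chrI", float(p), "+"): int(c)
                  for p, c in zip(positions, rng.integers(0, 9, 400))}
        t = DamageTrack(sample="cellular", counts=counts, convention="integer")
        dyad_pos = rng.choice(np.arange(100, 4900), size=100, replace=False)
        orients = rng.choice(["+", "-"], size=100)
        dyads = DyadMap(entries=[("chrI", int(p), o)
                                 for p, o in zip(dyad_pos, orients)])
        window = 30
        prof = dyad_align(t, dyads, window=window)
        # brute force: loop dyads x offsets
        for k in range(-window, window + 1):
            total, cover = 0, 0
            for (_, dpos, orient) in dyads.entries:
                sign = 1 if orient == "+" else -1
                p = float(dpos + sign * k)
                if ("chrI", p, "+") in counts:
                    total += counts[("chrI", p, "+")]
                    cover += 1
            assert prof.value_at(k) == total
            idx = np.nonzero(prof.offsets == k)[0][0]
            assert prof.weights[idx] == cover

    def test_raw_keyed_track_rejected(self):
        t = track({("chrI", 5.0, "+"): 1})
        with pytest.raises(ValueError):
            dyad_align(t, DyadMap(entries=[("chrI", 100, "+")]), window=10)


class TestEnrichment:
    def _profiles(self, cell, naked):
        offs = sorted(cell)
        c = PositionProfile("counts", np.array(offs, float),
                            np.array([cell[o] for o in offs], float))
        n = PositionProfile("counts", np.array(offs, float),
                            np.array([naked[o] for o in offs], float))
        return c, n

    def test_identical_tracks_give_unity(self):
        vals = {k: 5.0 + (k % 3) for k in range(-10, 11)}
        e = enrichment(*self._profiles(vals, vals))
        np.testing.assert_allclose(e.values, 1.0, atol=1e-12)

    def test_stated_formula_arithmetic(self):
        e = enrichment(*self._profiles({0: 20.0, 1: 10.0}, {0: 10.0, 1: 10.0}))
        assert e.value_at(0) == pytest.approx(4 / 3)
        assert e.value_at(1) == pytest.approx(2 / 3)

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(47)
        cell = {k: float(rng.integers(1, 50)) for k in range(-20, 21)}
        naked = {k: float(rng.integers(1, 50)) for k in range(-20, 21)}
        c, n = self._profiles(cell, naked)
        e1 = enrichment(c, n)
        c2 = PositionProfile("counts", c.offsets, c.values * 7.3)
        n2 = PositionProfile("counts", n.offsets, n.values * 0.11)
        e2 = enrichment(c2, n2)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-12)

    def test_zero_naked_emits_missing_not_infinity(self):
        e = enrichment(*self._profiles({0: 5.0, 1: 5.0, 2: 5.0},
                                       {0: 5.0, 1: 0.0, 2: 5.0}))
        assert np.isnan(e.value_at(1))
        assert np.isfinite(e.value_at(0))

    def test_naked_weighted_mean_is_one(self):
        rng = np.random.default_rng(53)
        cell = {k: float(rng.integers(1, 60)) for k in range(-30, 31)}
        naked = {k: float(rng.integers(1, 60)) for k in range(-30, 31)}
        e = enrichment(*self._profiles(cell, naked))
        wmean = np.average(e.values, weights=e.weights)
        assert wmean == pytest.approx(1.0, abs=1e-9)


class TestGeneratorRecovery:
    def test_null_enrichment_recovers_unity(self):
        spec = DamageSimSpec(n_dyads=120, enrichment_amp=0.0,
                             mean_coverage=8.0, seed=61)
        e, et = _recover(spec)
        # 3 Monte-Carlo sds from Poisson propagation
        assert np.nanmean(np.abs(e.values - 1.0) <= 3 * _sd(e)) > 0.97

    def test_implanted_curve_recovered_within_3sd(self, tmp_path):
        spec = DamageSimSpec(n_dyads=300, enrichment_amp=0.3,
                             enrichment_period=10.15, mean_coverage=5.0,
                             seed=67)
        e, et = _recover(spec)
        z = np.abs(e.values - et) / _sd(e)
        assert np.mean(z <= 3) > 0.97
        assert np.abs(np.nanmean(e.values - et)) < 3 * np.nanmean(_sd(e)) / np.sqrt(len(z))

    def test_fixed_seed_byte_identical_files(self, tmp_path):
        spec = DamageSimSpec(n_dyads=20, seed=3)
        files1 = [tmp_path / f"a_{n}.tsv" for n in "cnd"]
        files2 = [tmp_path / f"b_{n}.tsv" for n in "cnd"]
        gen_damage_data(spec, *files1)
        gen_damage_data(spec, *files2)
        for f1, f2 in zip(files1, files2):
            assert f1.read_bytes() == f2.read_bytes()

    def test_round_trip_through_track_files(self, tmp_path):
        spec = DamageSimSpec(n_dyads=10, seed=5)
        cell, naked, dyads = gen_damage_data(
            spec, tmp_path / "c.tsv", tmp_path / "n.tsv", tmp_path / "d.tsv")
        re_read = read_damage_track(tmp_path / "c.tsv")
        assert re_read.sample == "cellular"
        assert re_read.counts == cell.counts


def _recover(spec):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        cell, naked, dyads = gen_damage_data(
            spec, tmp / "c.tsv", tmp / "n.tsv", tmp / "d.tsv")
    ca = dyad_align(assign_lesions(cell, "half_integer"), dyads, spec.window)
    na = dyad_align(assign_lesions(naked, "half_integer"), dyads, spec.window)
    e = enrichment(ca, na)
    return e, spec.true_enrichment(e.offsets)


def _sd(e_profile):
    # Poisson error propagation for a ratio of aggregated counts
    n = np.maximum(e_profile.weights, 1.0)  # naked counts as weights
    return e_profile.values * np.sqrt(2.0 / n) + 1e-12
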