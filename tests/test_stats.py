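"""Introgression spectra, outlier thresholds, and rank/group tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invintro import stats
from invintro.coalescent import AncestryMatrix, SampleMap


def make_am(origin):
    origin = np.asarray(origin, dtype=np.uint8)
    n_ind = origin.shape[1] // 2
    samples = SampleMap(populations=[f"P{i}" for i in range(n_ind)],
                        demes=np.arange(n_ind),
                        distance_km=np.arange(n_ind) * 50.0)
    return AncestryMatrix(origin=origin, samples=samples)


class TestProportionsAndSpectrum:
    def test_all_focal_matrix(self):
        am = make_am(np.zeros((10, 20)))
        assert np.all(stats.individual_proportions(am) == 0)
        sp = stats.frequency_spectrum(am)
        assert sp.proportions[0] == 1.0
        assert sp.max_freq_pct == 0.0

    def test_single_homozygous_individual(self):
        origin = np.zeros((10, 20))
        origin[0, 2] = origin[0, 3] = 1  # both haplotypes of individual 1
        am = make_am(origin)
        props = stats.individual_proportions(am)
        assert props[1] == pytest.approx(10.0)
        assert np.all(np.delete(props, 1) == 0)

    def test_hand_counted_bins(self):
        origin = np.zeros((3, 20))
        origin[0, 0] = 1                      # 1/20 = 5%
        origin[1, 5] = 1                      # 5%
        origin[2, :10] = 1                    # 50%
        sp = stats.frequency_spectrum(make_am(origin))
        assert sp.proportions[1] == pytest.approx(2 / 3)   # 5% bin
        assert sp.proportions[10] == pytest.approx(1 / 3)  # 50% bin
        assert sp.max_freq_pct == pytest.approx(50.0)

    def test_per_individual_equals_mean_of_haplotype_indicators(self):
        rng = np.random.default_rng(0)
        origin = (rng.random((50, 20)) < 0.2).astype(np.uint8)
        am = make_am(origin)
        expected = origin.reshape(50, 10, 2).mean(axis=(0, 2)) * 100
        np.testing.assert_allclose(stats.individual_proportions(am), expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 60))
    def test_spectrum_mass_conservation(self, seed, n_markers):
        rng = np.random.default_rng(seed)
        origin = (rng.random((n_markers, 20)) < rng.random()).astype(np.uint8)
        sp = stats.frequency_spectrum(make_am(origin))
        assert sp.proportions.sum() == pytest.approx(1.0)
        assert sp.dosage_proportions.sum() == pytest.approx(1.0)
        assert np.all((0 <= sp.per_individual_pct) & (sp.per_individual_pct <= 100))


def brute_force_threshold(empirical, sims, q):
    """Independent oracle: literal scan of the 5% grid."""
    import math

    need = math.ceil(q * len(sims))
    for f in np.arange(5.0, 105.0, 5.0):
        emp = empirical.tail_proportion(f)
        lower = sum(1 for s in sims if s.tail_proportion(f) < emp)
        if lower >= need:
            return f
    return None


class TestOutlierThreshold:
    def toy_spectra(self, seed=0, n_sims=25):
        rng = np.random.default_rng(seed)
        sims = [stats.spectrum_from_frequencies(
            rng.choice([0, 5, 10, 15, 20], size=200, p=[.5, .3, .1, .07, .03]))
            for _ in range(n_sims)]
        emp = stats.spectrum_from_frequencies(
            np.concatenate([rng.choice([0, 5, 10], size=190), [40, 45, 45, 85, 90,
                                                               90, 95, 95, 90, 85]]))
        return emp, sims

    def test_three_replicate_toy(self):
        sims = [stats.spectrum_from_frequencies([0, 5, 10, 20] * 5)
                for _ in range(3)]
        emp = stats.spectrum_from_frequencies([0] * 99 + [40])
        res = stats.outlier_threshold(emp, sims, q=0.95)
        # simulations have no mass at/above 25%; empirical has 0.01 at 40%
        assert res.sign_threshold_pct == 25.0

    def test_identical_empirical_and_sims_has_no_threshold(self):
        spec = stats.spectrum_from_frequencies([0, 5, 10, 20] * 5)
        res = stats.outlier_threshold(spec, [spec] * 30, q=0.95)
        assert res.sign_threshold_pct is None

    def test_equals_brute_force_scan(self):
        for seed in range(5):
            emp, sims = self.toy_spectra(seed)
            res = stats.outlier_threshold(emp, sims, q=0.95)
            assert res.sign_threshold_pct == brute_force_threshold(emp, sims, 0.95)

    def test_monotone_in_q(self):
        emp, sims = self.toy_spectra(3)
        taus = []
        for q in (0.5, 0.8, 0.95, 1.0):
            r = stats.outlier_threshold(emp, sims, q=q)
            taus.append(r.sign_threshold_pct if r.sign_threshold_pct is not None
                        else 200.0)
        assert all(b >= a for a, b in zip(taus, taus[1:]))

    def test_global_threshold_is_max(self):
        emp, sims = self.toy_spectra(1)
        r1 = stats.outlier_threshold(emp, sims, q=0.95)
        r2 = stats.outlier_threshold(emp, sims, q=0.5)
        assert stats.global_threshold([r1, r2]) == max(r1.sign_threshold_pct,
                                                       r2.sign_threshold_pct)


class TestGradientTest:
    def test_perfect_gradients(self):
        d = np.arange(10.0)
        rho, p = stats.gradient_test(np.arange(10.0), d)
        assert rho == pytest.approx(1.0)
        rho2, _ = stats.gradient_test(np.arange(10.0)[::-1], d)
        assert rho2 == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        rho, p = stats.gradient_test(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.random(6)
        y = rng.random(6)
        _, p = stats.gradient_test(x, y)
        # oracle: direct enumeration over all orderings of x
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(rx):
            r = np.corrcoef(perm, ry)[0, 1]
            hits += abs(r) >= obs - 1e-12
            total += 1
        assert p == pytest.approx(hits / total)

    def test_exact_p_perfect_order_n10(self):
        # only 2 of 10! orderings achieve |rho| = 1
        _, p = stats.gradient_test(np.arange(10.0), np.arange(10.0))
        assert p == pytest.approx(2 / 3628800)


class TestGroupCompare:
    def test_identical_groups(self):
        u, p = stats.group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.01)

    def test_fully_separated_three_vs_three(self):
        u, p = stats.group_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)   # 2 / C(6,3)

    def test_planted_tenfold_difference(self):
        rng = np.random.default_rng(1)
        autos = rng.normal(2.0, 0.3, size=20)
        x_chr = rng.normal(0.2, 0.05, size=8)
        _, p = stats.group_compare(x_chr, autos)
        assert p < 0.01


class TestMtdnaLikeScreen:
    def test_boundary_cases(self):
        southern = np.array([True] * 10 + [False] * 10)
        calls = np.zeros((3, 20))
        calls[0, 10:12] = 1          # clean south, 2 northern: flagged
        calls[1, 0] = 1              # one southern introgressed: rejected
        calls[1, 10:15] = 1
        calls[2, 10] = 1             # only one northern: rejected
        flags, skipped = stats.mtdna_like_screen(calls, southern)
        assert list(flags) == [True, False, False]
        assert skipped == []

    def test_missing_calls_are_skipped_with_notice(self):
        southern = np.array([True] * 10 + [False] * 10)
        calls = np.zeros((2, 20))
        calls[0, 10:12] = 1
        calls[1, 3] = np.nan
        flags, skipped = stats.mtdna_like_screen(calls, southern)
        assert flags[0] == True  # noqa: E712
        assert flags.mask[1]
        assert skipped == [1]

    def test_planted_windows_round_trip(self):
        from invintro import synth

        plan = synth.SynthPlan(
            chromosomes={"chr1": 100}, seed=2, n_null_markers=0,
            tract_plan=[synth.TractPlan("chr1", 0, 10, 0.15, "mtdna-like"),
                        synth.TractPlan("chr1", 20, 30, 0.10, "uniform"),
                        synth.TractPlan("chr1", 40, 50, 0.25, "mtdna-like")])
        data = synth.simulate_haplotypes(plan)
        am = data.truth_matrix()
        southern = np.array([True] * 10 + [False] * 10)
        flags, _ = stats.mtdna_like_screen(am.origin.astype(float), southern)
        patterns = [tp.pattern for tp, _ in data.realized]
        for flag, pat in zip(flags, patterns):
            if pat == "mtdna-like":
                assert flag
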