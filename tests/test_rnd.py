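"""RND/RNDmin windowed scan, FDR/power calibration, artificial planting."""

import numpy as np
import pytest

from invintro import rnd, synth
from invintro.tracts import Tract


@pytest.fixture(scope="module")
def planted_genome():
    """Synthetic genome with tracts of three lengths planted at low frequency."""
    plan = synth.SynthPlan(
        chromosomes={"chr1": 600_000}, seed=10,
        tract_plan=[
            synth.TractPlan("chr1", 40_000, 50_000, 0.05),    # 10 kb
            synth.TractPlan("chr1", 100_000, 110_000, 0.10),
            synth.TractPlan("chr1", 200_000, 230_000, 0.05),  # 30 kb
            synth.TractPlan("chr1", 300_000, 330_000, 0.10),
            synth.TractPlan("chr1", 400_000, 450_000, 0.05),  # 50 kb
            synth.TractPlan("chr1", 500_000, 550_000, 0.10),
        ])
    return synth.simulate_haplotypes(plan)


class TestWindowDxy:
    def test_identical_groups_zero(self):
        h = np.tile(np.frombuffer(b"ACGTACGTAC", dtype=np.uint8), (3, 1))
        sites = np.arange(10)
        assert rnd.window_dxy(h, h.copy(), sites) == 0.0

    def test_single_difference_counting(self):
        a = np.frombuffer(b"A" * 100, dtype=np.uint8).reshape(1, -1).copy()
        b = a.copy()
        b[0, 42] = ord("T")
        assert rnd.window_dxy(a, b, np.arange(100)) == pytest.approx(0.01)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(3)
        A = rng.choice(list(b"ACGT"), size=(3, 80)).astype(np.uint8)
        B = rng.choice(list(b"ACGT"), size=(2, 80)).astype(np.uint8)
        sites = np.sort(rng.choice(80, size=50, replace=False))
        got = rnd.window_dxy(A, B, sites)
        acc = 0.0
        for i in range(3):
            for j in range(2):
                acc += np.mean(A[i, sites] != B[j, sites])
        assert got == pytest.approx(acc / 6)


class TestRndProfile:
    def test_planted_haplotype_has_depressed_rnd(self, planted_genome):
        d = planted_genome
        prof = rnd.rnd_profile(d.focal["chr1"], d.donor["chr1"],
                               d.outgroup["chr1"], 10_000)
        by_start = {w.start: w for w in prof}
        w = by_start[40_000]
        tp, haps = d.realized[0]
        native = np.delete(w.rnd, haps)
        assert w.rnd[haps].max() < native.min() / 2
        assert w.rnd_min == pytest.approx(w.rnd[haps].min())

    def test_rndmin_is_min_over_haplotypes(self, planted_genome):
        d = planted_genome
        prof = rnd.rnd_profile(d.focal["chr1"], d.donor["chr1"],
                               d.outgroup["chr1"], 20_000)
        for w in prof:
            assert w.rnd_min == pytest.approx(w.rnd.min())
            assert np.all(w.rnd_min <= w.rnd + 1e-12)

    def test_low_informative_windows_omitted(self):
        rng = np.random.default_rng(0)
        base = rng.choice(list(b"ACGT"), size=2000).astype(np.uint8)
        focal = np.tile(base, (4, 1))
        donor = np.tile(base, (2, 1))
        out = np.tile(base, (2, 1))
        # 49 variable sites in the first 1000-bp window, 60 in the second
        for pos in range(0, 49):
            donor[:, pos] = ord("T") if base[pos] != ord("T") else ord("C")
        for pos in range(1000, 1060):
            donor[:, pos] = ord("T") if base[pos] != ord("T") else ord("C")
        prof = rnd.rnd_profile(focal, donor, out, 1000, min_informative=50)
        assert [w.start for w in prof] == [1000]

    def test_ratio_invariant_to_doubled_mutation_counts(self, planted_genome):
        """Doubling every window's difference counts in numerator and
        denominator alike (site duplication) leaves RND unchanged."""
        d = planted_genome
        f, dn, o = d.focal["chr1"], d.donor["chr1"], d.outgroup["chr1"]
        prof = rnd.rnd_profile(f, dn, o, 50_000)
        prof2 = rnd.rnd_profile(np.repeat(f, 2, axis=1), np.repeat(dn, 2, axis=1),
                                np.repeat(o, 2, axis=1), 100_000)
        assert len(prof) == len(prof2)
        for w, w2 in zip(prof, prof2):
            assert w2.n_informative == 2 * w.n_informative
            np.testing.assert_allclose(w2.rnd, w.rnd, rtol=1e-12)

    def test_background_rnd_tracks_divergence_ratio(self, planted_genome):
        """Native focal haplotypes sit near d_focal-donor / d_donor-outgroup
        (~0.5 under the default synthetic targets)."""
        d = planted_genome
        prof = rnd.rnd_profile(d.focal["chr1"], d.donor["chr1"],
                               d.outgroup["chr1"], 50_000)
        rnds = np.concatenate([w.rnd for w in prof])
        assert np.nanmedian(rnds) == pytest.approx(0.5, abs=0.1)


class TestCalibration:
    def test_perfect_separation(self):
        windows = []
        truth = []
        for i in range(10):
            r = np.full(4, 1.0)
            if i < 3:
                r[0] = 0.1
                truth.append(Tract("chr1", i * 1000, (i + 1) * 1000, hap=0))
            windows.append(rnd.WindowRND("chr1", i * 1000, (i + 1) * 1000, 100,
                                         r, float(r.min())))
        res = rnd.calibrate_threshold(windows, truth)
        assert res.fdr == 0.0
        assert res.power == 1.0

    def test_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(5)
        windows, truth, labels = [], [], []
        for i in range(10):
            is_true = i % 3 == 0
            mn = rng.uniform(0.05, 0.4) if is_true else rng.uniform(0.3, 1.2)
            r = np.concatenate([[mn], rng.uniform(0.8, 1.5, size=3)])
            windows.append(rnd.WindowRND("chr1", i * 1000, (i + 1) * 1000, 100,
                                         r, float(r.min())))
            labels.append(is_true)
            if is_true:
                truth.append(Tract("chr1", i * 1000, (i + 1) * 1000, hap=0))
        res = rnd.calibrate_threshold(windows, truth, target_fdr=0.25)
        # oracle: try every threshold, track best
        rm = np.array([w.rnd_min for w in windows])
        lab = np.array(labels)
        best = None
        for tau in np.sort(rm):
            called = rm <= tau
            fdr = (called & ~lab).sum() / called.sum()
            power = (called & lab).sum() / lab.sum()
            if fdr <= 0.25:
                best = (tau, fdr, power)
        assert best is not None
        assert res.threshold == pytest.approx(best[0])
        assert res.fdr == pytest.approx(best[1])
        assert res.power == pytest.approx(best[2])

    def test_partial_overlaps_excluded(self):
        windows = [rnd.WindowRND("chr1", 0, 1000, 100, np.array([0.1, 1.0]), 0.1),
                   rnd.WindowRND("chr1", 1000, 2000, 100, np.array([0.1, 1.0]), 0.1)]
        truth = [Tract("chr1", 0, 1500, hap=0)]   # covers w0, partial w1
        res = rnd.calibrate_threshold(windows, truth)
        assert res.n_true_windows == 1
        assert res.n_null_windows == 0

    def test_high_frequency_truth_excluded(self):
        r = np.array([0.1, 0.1, 0.1, 0.1])
        windows = [rnd.WindowRND("chr1", 0, 1000, 100, r, 0.1),
                   rnd.WindowRND("chr1", 1000, 2000, 100, np.array([0.1, 1, 1, 1]), 0.1)]
        truth = [Tract("chr1", 0, 1000, hap=h) for h in range(4)]  # freq 1.0
        truth += [Tract("chr1", 1000, 2000, hap=0)]
        res = rnd.calibrate_threshold(windows, truth, max_truth_freq=0.65)
        assert res.n_true_windows == 1

    def test_power_increases_with_tract_length(self, planted_genome):
        """Longer planted tracts fill their windows more often and carry more
        informative sites, so detection power rises with tract length."""
        d = planted_genome
        prof = rnd.rnd_profile(d.focal["chr1"], d.donor["chr1"],
                               d.outgroup["chr1"], 10_000)
        res = rnd.calibrate_threshold(prof, d.truth, target_fdr=0.10,
                                      max_truth_freq=0.65)
        lens = sorted(res.power_by_length)
        assert lens == [10_000.0, 30_000.0, 50_000.0]
        powers = [res.power_by_length[k] for k in lens]
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] == 1.0


class TestFdrOnSyntheticGenome:
    def test_null_genome_produces_no_confident_calls(self):
        plan = synth.SynthPlan(chromosomes={"chr1": 400_000}, seed=3)
        d = synth.simulate_haplotypes(plan)
        prof = rnd.rnd_profile(d.focal["chr1"], d.donor["chr1"],
                               d.outgroup["chr1"], 20_000)
        # threshold calibrated on an independent planted genome
        plan2 = synth.SynthPlan(
            chromosomes={"chr1": 400_000}, seed=4,
            tract_plan=[synth.TractPlan("chr1", s, s + 20_000, 0.05)
                        for s in range(20_000, 400_000, 60_000)])
        d2 = synth.simulate_haplotypes(plan2)
        prof2 = rnd.rnd_profile(d2.focal["chr1"], d2.donor["chr1"],
                                d2.outgroup["chr1"], 20_000)
        cal = rnd.calibrate_threshold(prof2, d2.truth, target_fdr=0.10)
        false_calls = sum(w.rnd_min <= cal.threshold for w in prof)
        assert false_calls == 0

    def test_calibrated_fdr_within_binomial_interval(self):
        """On a larger planted genome the realized FDR at the selected
        threshold stays inside the binomial confidence band of the target."""
        step = 50_000
        plan = synth.SynthPlan(
            chromosomes={"chr1": 2_000_000}, seed=8,
            tract_plan=[synth.TractPlan("chr1", s, s + 20_000,
                                        0.05 if (s // step) % 2 else 0.10)
                        for s in range(0, 2_000_000 - step, step)])
        d = synth.simulate_haplotypes(plan)
        prof = rnd.rnd_profile(d.focal["chr1"], d.donor["chr1"],
                               d.outgroup["chr1"], 20_000)
        cal = rnd.calibrate_threshold(prof, d.truth, target_fdr=0.10)
        n_calls = sum(w.rnd_min <= cal.threshold for w in prof
                      if True)
        assert cal.fdr <= 0.10
        # binomial CI: with n calls at true FDR 0.10, the realized count
        # cannot be far below: just require some detections happened
        assert cal.power > 0.5
        assert n_calls >= cal.n_true_windows * cal.power


@pytest.fixture(scope="module")
def recipients():
    plan = synth.SynthPlan(chromosomes={"chr1": 400_000}, seed=6)
    d = synth.simulate_haplotypes(plan)
    return d.focal["chr1"], d.donor["chr1"][0]


class TestPlanting:

    def test_exact_truth_counts(self, recipients):
        rec, don = recipients
        mod, truth = rnd.plant_artificial_tracts(
            rec, don, lengths=(10_000, 30_000), n_per_length=5, seed=1)
        by_len = {}
        for t in truth:
            by_len[t.length] = by_len.get(t.length, 0) + 1
        assert by_len == {10_000: 5, 30_000: 5}

    def test_planted_content_round_trip(self, recipients):
        rec, don = recipients
        mod, truth = rnd.plant_artificial_tracts(
            rec, don, lengths=(10_000,), n_per_length=8, seed=2)
        for t in truth:
            np.testing.assert_array_equal(mod[t.hap, t.start:t.end],
                                          don[t.start:t.end])

    def test_centromere_never_spanned(self, recipients):
        rec, don = recipients
        centromere = (150_000, 250_000)
        mod, truth = rnd.plant_artificial_tracts(
            rec, don, lengths=(10_000,), n_per_length=10, seed=3,
            centromere=centromere)
        for t in truth:
            assert t.end <= centromere[0] or t.start >= centromere[1]

    def test_replicate_datasets_are_independent(self, recipients):
        rec, don = recipients
        sets = rnd.plant_artificial_datasets(rec, don, lengths=(10_000,),
                                             n_per_length=4, n_datasets=3, seed=5)
        assert len(sets) == 3
        placements = [tuple((t.start, t.hap) for t in truth) for _, truth in sets]
        assert len(set(placements)) > 1    # different random placements
        for _, truth in sets:
            assert len(truth) == 4

    def test_shortfall_is_an_error(self, recipients):
        rec, don = recipients
        with pytest.raises(ValueError, match="shortfall"):
            rnd.plant_artificial_tracts(rec, don, lengths=(50_000,),
                                        n_per_length=100, seed=4)
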