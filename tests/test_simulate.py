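"""Generator contracts: degenerate cases, distributional laws, determinism."""

import numpy as np
import pytest
from scipy import stats

import pausekit as pk
from pausekit.simulate import sample_discrete


class TestScRNAGenerator:
    def test_degenerate_distributions_give_identical_reads(self, plus_gene, point_params):
        reads = pk.generate_scrna_reads([plus_gene], point_params, 10)
        assert len(reads) == 10
        for r in reads:
            assert r.five_prime == plus_gene.true_tss
            assert r.three_prime == plus_gene.true_tss + 34
            assert r.length == 34

    def test_minus_strand_reads_are_mirrored(self, minus_gene, point_params):
        reads = pk.generate_scrna_reads([minus_gene], point_params, 5)
        for r in reads:
            assert r.five_prime == minus_gene.true_tss
            assert r.three_prime == minus_gene.true_tss - 34
            assert r.length == 34

    def test_pause_offsets_follow_multinomial_law(self, plus_gene):
        """Uniform mass on {33,34,35}: each empirical share within 3 sigma of 1/3."""
        n = 30_000
        params = pk.KineticParams(tss_jitter_dist={0: 1.0}, seed=3)
        reads = pk.generate_scrna_reads([plus_gene], params, n)
        offsets = np.array([r.three_prime - plus_gene.true_tss for r in reads])
        sigma = np.sqrt((1 / 3) * (2 / 3) / n)
        for off in (33, 34, 35):
            assert abs(np.mean(offsets == off) - 1 / 3) < 3 * sigma

    def test_antisense_count_is_binomial(self, plus_gene, default_params):
        n, frac = 10_000, 0.3
        reads = pk.generate_scrna_reads(
            [plus_gene], default_params, n, antisense_fraction=frac
        )
        n_anti = sum(r.strand == "-" for r in reads)
        assert abs(n_anti - frac * n) < 3 * np.sqrt(n * frac * (1 - frac))

    def test_empirical_pause_distribution_converges(self, plus_gene):
        """Total variation to the generating pmf < 0.02 at n = 100,000."""
        params = pk.KineticParams(tss_jitter_dist={0: 1.0}, seed=5)
        reads = pk.generate_scrna_reads([plus_gene], params, 100_000)
        offsets = np.array([r.three_prime - plus_gene.true_tss for r in reads])
        tvd = 0.5 * sum(
            abs(np.mean(offsets == k) - p)
            for k, p in params.pause_offset_dist.items()
        )
        assert tvd < 0.02

    def test_deterministic_given_seed(self, plus_gene, default_params):
        a = pk.generate_scrna_reads([plus_gene], default_params, 500)
        b = pk.generate_scrna_reads([plus_gene], default_params, 500)
        assert a == b

    def test_empty_gene_list_errors(self, default_params):
        with pytest.raises(ValueError):
            pk.generate_scrna_reads([], default_params, 10)

    def test_impossible_length_window_errors(self, plus_gene):
        params = pk.KineticParams(
            pause_offset_dist={5: 1.0}, tss_jitter_dist={0: 1.0}, seed=1
        )
        with pytest.raises(RuntimeError, match="redraws"):
            pk.generate_scrna_reads([plus_gene], params, 10, max_redraws=10)


class TestChIPGenerator:
    def test_point_mass_mixture_occupies_exactly_two_offsets(self, plus_gene):
        shear = pk.ShearBiasParams(
            mixture_centers=(0, 110), mixture_sds=(0, 0),
            mixture_weights=(0.5, 0.5), seed=2,
        )
        frags = pk.generate_chip_fragments([plus_gene], shear, 1000)
        centers = {f.center - plus_gene.true_tss for f in frags}
        assert centers == {0, 110}

    def test_mechanistic_mode_keeps_endpoints_out_of_footprint(self, plus_gene):
        shear = pk.ShearBiasParams(
            mode="mechanistic", footprint_center=34, footprint_halfwidth=14, seed=3
        )
        frags = pk.generate_chip_fragments([plus_gene], shear, 5000)
        for f in frags:
            for endpoint in (f.start, f.end):
                assert not (
                    plus_gene.true_tss + 21 <= endpoint <= plus_gene.true_tss + 47
                )

    def test_mechanistic_centers_bimodal_flanking_footprint(self, plus_gene):
        """Sampler matches the brute-force enumeration of allowed pieces.

        With a discrete length pmf the expected center histogram is exact:
        upstream pieces abut the footprint's left edge, downstream pieces
        its right edge, spanning pieces cover it.  Both the enumerated and
        the sampled 25-bp profiles must be bimodal around the footprint.
        """
        length_pmf = {100: 0.5, 150: 0.5}
        fc, hw = 34, 14
        lo, hi = fc - hw, fc + hw
        shear = pk.ShearBiasParams(
            mode="mechanistic", footprint_center=fc, footprint_halfwidth=hw,
            fragment_length_dist=length_pmf, span_weight=0.2, seed=4,
        )
        # brute-force enumeration of allowed (piece, length, overhang) combos
        exp_hist = {}
        for L, pL in length_pmf.items():
            c_up = (lo - L + lo) // 2
            c_down = (hi + hi + L) // 2
            exp_hist[c_up] = exp_hist.get(c_up, 0) + 0.4 * pL
            exp_hist[c_down] = exp_hist.get(c_down, 0) + 0.4 * pL
            for u in range(L - (hi - lo) + 1):
                c = (2 * (lo - u) + L) // 2
                w = 0.2 * pL / (L - (hi - lo) + 1)
                exp_hist[c] = exp_hist.get(c, 0) + w
        exp_centers = np.array(sorted(exp_hist))
        up_mass = sum(v for c, v in exp_hist.items() if c < lo)
        down_mass = sum(v for c, v in exp_hist.items() if c > hi)
        mid_mass = sum(v for c, v in exp_hist.items() if lo <= c <= hi)
        assert up_mass > mid_mass and down_mass > mid_mass  # bimodal flanks
        frags = pk.generate_chip_fragments([plus_gene], shear, 50_000)
        offs = np.array([f.center - plus_gene.true_tss for f in frags])
        assert set(np.unique(offs)) <= set(exp_centers.tolist())
        # sampled masses match enumeration within 3-sigma binomial error
        for region, mass in (
            (offs < lo, up_mass), (offs > hi, down_mass),
        ):
            se = np.sqrt(mass * (1 - mass) / len(offs))
            assert abs(region.mean() - mass) < 3 * se

    def test_footprint_wider_than_fragments_errors(self, plus_gene):
        shear = pk.ShearBiasParams(
            mode="mechanistic", footprint_halfwidth=200,
            fragment_length_dist={100: 1.0}, seed=1,
        )
        with pytest.raises(ValueError, match="wider"):
            pk.generate_chip_fragments([plus_gene], shear, 10)


class TestLaneGenerator:
    SEQ = "ATTGACTTAGCTTACGTTAGGCTTAACTGTTA"

    def test_zero_fraction_is_flat_background(self):
        lane = pk.generate_lane_profile(
            -10, 22, self.SEQ, (0, 10), 0.0, background=2.0, noise_sd=0.0
        )
        assert np.allclose(lane.intensities, 2.0)

    def test_signal_is_linear_in_fraction_by_construction(self):
        full = pk.generate_lane_profile(-10, 22, self.SEQ, (0, 10), 1.0)
        half = pk.generate_lane_profile(-10, 22, self.SEQ, (0, 10), 0.5)
        in_bubble = (full.offsets >= 0) & (full.offsets <= 10) & full.is_thymine
        assert np.allclose(
            full.intensities[in_bubble] - 2.0,
            2.0 * (half.intensities[in_bubble] - 2.0),
        )

    def test_least_squares_recovers_gain_and_background(self):
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        sums = []
        for f in fractions:
            lane = pk.generate_lane_profile(
                -10, 22, self.SEQ, (0, 10), f, background=2.0, gain=10.0
            )
            in_bubble = (lane.offsets >= 0) & (lane.offsets <= 10) & lane.is_thymine
            sums.append(lane.intensities[in_bubble].sum())
        n_t = int(in_bubble.sum())
        slope, intercept, r, *_ = stats.linregress(fractions, sums)
        assert slope == pytest.approx(10.0 * n_t, abs=1e-9)
        assert intercept == pytest.approx(2.0 * n_t, abs=1e-9)
        assert r**2 == pytest.approx(1.0, abs=1e-12)

    def test_fraction_out_of_range_errors(self):
        with pytest.raises(ValueError):
            pk.generate_lane_profile(-10, 22, self.SEQ, (0, 10), 1.5)


class TestDecayGenerator:
    def test_halving_law_noiseless(self):
        s = pk.generate_decay_series(10.0, [0, 10, 20, 30], n_replicates=1)
        assert np.allclose(s.replicate_values[0], [1.0, 0.5, 0.25, 0.125])

    def test_memorylessness_of_exponential_decay(self):
        s = pk.generate_decay_series(7.0, [0, 4, 9, 13], n_replicates=1)
        v = dict(zip(s.times, s.replicate_values[0]))
        assert v[13.0] == pytest.approx(v[4.0] * v[9.0], rel=1e-12)

    def test_replicate_means_track_noiseless_curve(self):
        n_rep, sd = 3, 0.05
        s = pk.generate_decay_series(10.0, [0, 5, 10, 20], n_rep, sd, seed=9)
        clean = 2.0 ** (-s.times / 10.0)
        means = s.replicate_values.mean(axis=0)
        # multiplicative noise: sd of the mean is sd * value / sqrt(n)
        assert np.all(np.abs(means - clean) < 3 * sd * clean / np.sqrt(n_rep))

    def test_negative_times_error(self):
        with pytest.raises(ValueError):
            pk.generate_decay_series(10.0, [-5, 0, 10])


class TestGeneTableAndOccupancySim:
    def test_point_mass_scores_identical(self):
        t = pk.generate_gene_table(10, ("point", {"value": 3.0}), seed=1)
        assert len(t) == 10
        assert (t.promoter_enrichment_score == 3.0).all()

    def test_lognormal_unique_ids_positive_scores(self):
        t = pk.generate_gene_table(1000, seed=2)
        assert t.gene_id.is_unique
        assert (t.promoter_enrichment_score > 0).all()

    def test_fixed_seed_reproducible(self):
        a = pk.generate_gene_table(50, seed=3)
        b = pk.generate_gene_table(50, seed=3)
        assert a.equals(b)

    def test_two_state_simulator_matches_closed_form(self):
        k_init, t_half, n = 0.05, 10.0, 10_000
        frac = pk.simulate_two_state_occupancy(k_init, t_half, n, seed=4)
        p = pk.steady_state_occupancy(k_init, t_half)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_sample_discrete_pmf_and_normal_spec(rng):
    vals = sample_discrete(rng, {1: 0.5, 9: 0.5}, 1000)
    assert set(np.unique(vals)) == {1, 9}
    vals = sample_discrete(rng, ("normal", {"mean": 200, "sd": 50, "min": 50}), 1000)
    assert vals.min() >= 50
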