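"""Synthetic-data generators: reproducibility and agreement with theory."""

import numpy as np
import pandas as pd
import pytest

from ratemix import entropy
from ratemix.popgen import WindowScheme, windowed_stats
from ratemix.simulate import (
    im_pair_fst,
    pair_rate_ratio,
    simulate_block_ancestry,
    simulate_im_landscape,
    simulate_im_pair,
    simulate_site_patterns,
    simulate_stepping_stone,
    stepping_stone_r_fst,
)
from ratemix.sitepatterns import d3 as d3_stat
from ratemix.theory import RecurrentMutationParams, d3_observed, fst_equilibrium, sojourn_times


class TestReproducibility:
    def test_same_seed_same_realization(self):
        a = simulate_im_pair(500, 100, 0.01, 1e-3, 2e-3, seed=42)
        b = simulate_im_pair(500, 100, 0.01, 1e-3, 2e-3, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_im_pair(500, 100, 0.01, 1e-3, 2e-3, seed=42)
        b = simulate_im_pair(500, 100, 0.01, 1e-3, 2e-3, seed=43)
        assert not a.equals(b)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            simulate_im_pair(10, 100, 0.01, 1e-3, 2e-3, seed=None)

    def test_landscape_deterministic(self):
        kwargs = dict(
            classes=[{"fst": 0.3, "n_windows": 3}], N=100, n_per_pop=2, loci_per_window=5
        )
        a = simulate_im_landscape(seed=7, **kwargs)
        b = simulate_im_landscape(seed=7, **kwargs)
        assert np.array_equal(a.table.gt, b.table.gt)
        assert np.array_equal(a.table.pos, b.table.pos)


class TestPairEngine:
    def test_symmetric_rates_give_unit_ratio(self):
        rec = simulate_im_pair(50_000, 100, 0.0025, 1e-3, 1e-3, seed=1)
        r, se = pair_rate_ratio(rec)
        assert abs(r - 1.0) < 3 * se

    def test_rate_mixing_at_intermediate_divergence(self):
        # 4Nm = 1 (FST = 0.5), r0 = 2: the closed form gives r = 1.4
        rec = simulate_im_pair(100_000, 100, 0.0025, 1e-3, 2e-3, seed=2)
        r, se = pair_rate_ratio(rec)
        assert abs(r - 1.4) < 3 * se

    def test_sojourn_moments_match_closed_forms(self):
        N, m = 100, 0.0025
        rec = simulate_im_pair(50_000, N, m, 1e-3, 1e-3, seed=3)
        s = sojourn_times(N, m)
        n = len(rec)
        for col, expected in (("t1_pop1", s.s11), ("t2_pop1", s.s21), ("t2_pop2", s.s22)):
            mc_se = rec[col].std(ddof=1) / np.sqrt(n)
            assert abs(rec[col].mean() - expected) < 3 * mc_se

    def test_empirical_fst_matches_equilibrium(self):
        fst, se = im_pair_fst(50_000, 100, 0.0025, 1e-3, 2e-3, seed=4)
        assert abs(fst - 0.5) < 3 * se

    def test_coalescence_times_match_msprime(self):
        # independent oracle: msprime's two-island model with haploid scaling
        import msprime

        N, m, reps = 100, 0.005, 4000
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=N)
        dem.add_population(name="B", initial_size=N)
        dem.set_symmetric_migration_rate(["A", "B"], m)
        tb = np.array(
            [
                ts.first().time(ts.first().root)
                for ts in msprime.sim_ancestry(
                    samples={"A": 1, "B": 1}, ploidy=1, demography=dem,
                    num_replicates=reps, random_seed=9,
                )
            ]
        )
        rec = simulate_im_pair(reps, N, m, 1e-3, 1e-3, seed=10)
        se = np.sqrt(tb.var(ddof=1) / reps + rec.t_coal.var(ddof=1) / reps)
        assert abs(tb.mean() - rec.t_coal.mean()) < 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_im_pair(10, -5, 0.01, 1e-3, 1e-3, seed=1)
        with pytest.raises(ValueError):
            simulate_im_pair(10, 100, 0.01, 1e-3, 1e-3, seed=1, sampling="elsewhere")


class TestSteppingStone:
    def test_two_demes_match_im_pair_moments(self):
        ss = simulate_stepping_stone(30_000, 2, 100, 0.0025, 0.0025, 1e-3, 2e-3, seed=5)
        im = simulate_im_pair(30_000, 100, 0.0025, 1e-3, 2e-3, seed=6)
        n = len(ss)
        se = np.sqrt(ss.t_coal.var(ddof=1) / n + im.t_coal.var(ddof=1) / n)
        assert abs(ss.t_coal.mean() - im.t_coal.mean()) < 3 * se
        r_ss, se_ss = pair_rate_ratio(ss)
        r_im, se_im = pair_rate_ratio(im)
        assert abs(r_ss - r_im) < 3 * np.hypot(se_ss, se_im)

    def test_symmetric_chain_with_equal_rates_is_null(self):
        res = stepping_stone_r_fst(20_000, 6, 100, 0.01, 0.01, 1e-3, 1e-3, seed=7)
        assert abs(res["r"] - 1.0) < 3 * res["r_se"]

    def test_within_species_structure_underestimates_rate_divergence(self):
        # strong internal structure inflates FST without adding rate
        # divergence, so (r-1)/(r0-1) falls short of FST
        res = stepping_stone_r_fst(30_000, 4, 100, 0.001, 0.01, 1e-3, 2e-3, seed=8)
        remaining = (res["r"] - 1.0) / (2.0 - 1.0)
        assert remaining + 3 * res["r_se"] < res["fst"]

    def test_disconnected_chain_rejected(self):
        with pytest.raises(ValueError):
            simulate_stepping_stone(10, 4, 100, 0.01, 0.0, 1e-3, 1e-3, seed=9)


class TestSitePatternSim:
    def test_no_recurrent_mutation_leaves_counts_unchanged(self):
        # without recurrent mutation no site is dropped or flipped, and the
        # mean D3 over replicates matches the true asymmetry within the
        # analytic binomial Monte-Carlo error
        n1, n2, reps = 4000, 6000, 20
        estimates = []
        for seed in range(reps):
            df = simulate_site_patterns(n1, n2, p1=0.0, c=0.5, seed=seed)
            assert df["abb"].sum() + df["bab"].sum() == n1 + n2
            estimates.append(d3_stat(df).estimate)
        f1 = n1 / (n1 + n2)
        mc_se = np.sqrt(4 * f1 * (1 - f1) / (n1 + n2) / reps)
        assert abs(np.mean(estimates) - (-0.2)) < 3 * mc_se

    def test_symmetric_truth_stays_symmetric(self):
        df = simulate_site_patterns(30_000, 30_000, p1=0.15, c=0.6, seed=2)
        est = d3_stat(df)
        assert abs(est.estimate) < 3 * est.se

    def test_matches_recurrent_mutation_theory(self):
        truth = d3_observed(RecurrentMutationParams(p1=0.1, c=0.5, d3_true=-0.2))
        df = simulate_site_patterns(40_000, 60_000, p1=0.1, c=0.5, seed=3)
        est = d3_stat(df)
        assert abs(est.estimate - truth) < 3 * est.se

    def test_four_taxon_columns_present(self):
        df = simulate_site_patterns(500, 500, p1=0.1, c=0.5, p2=0.3, seed=4)
        assert {"abba", "baba"} <= set(df.columns)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            simulate_site_patterns(10, 10, p1=1.5, c=0.5, seed=1)


class TestBlockAncestry:
    def test_shapes_and_alphabet(self):
        d = simulate_block_ancestry(100, 0.01, 0.5, 3, 4, seed=1)
        assert d.shape == (4, 3, 100)
        assert set(np.unique(d)) <= {0.0, 0.5, 1.0}

    def test_degenerate_contribution_gives_constant_zero_entropy(self):
        for q in (0.0, 1.0):
            d = simulate_block_ancestry(200, 0.0, q, 3, 2, seed=2)
            z = np.exp(1j * np.arctan2(1 - d, d))
            assert np.allclose(entropy.within_entropy_batch(z), 0.0, atol=1e-12)
            assert entropy.between_entropy(z[0]).sb == pytest.approx(0.0, abs=1e-12)

    def test_iid_limit_is_the_entropy_maximum_of_the_sweep(self):
        # fully disassociated 50/50 ancestry is the randomness endpoint:
        # both entropies are largest there.  (Sb stays below ln J because
        # i.i.d. phasors with balanced dosage retain a common mean, hence
        # nonzero average cross-correlation.)
        J, reps = 6, 50

        def entropies(d_prob, seed):
            d = simulate_block_ancestry(1000, d_prob, 0.5, J, reps, seed=seed)
            z = np.exp(1j * np.arctan2(1 - d, d))
            sw = entropy.within_entropy_batch(z).mean()
            sb = np.mean([entropy.between_entropy(z[r]).sb for r in range(reps)])
            return sw, sb

        sw_lo, sb_lo = entropies(0.01, seed=3)
        sw_hi, sb_hi = entropies(1.0, seed=3)
        assert sw_hi > sw_lo
        assert sb_hi > sb_lo
        assert sb_hi <= np.log(J) + 1e-9

    def test_zero_disassociation_yields_single_block(self):
        d = simulate_block_ancestry(300, 0.0, 0.5, 4, 10, seed=4)
        assert np.all(d == d[..., :1])


class TestLandscape:
    def test_single_class_fst_centered_on_equilibrium(self):
        land = simulate_im_landscape(
            seed=7,
            classes=[{"fst": 0.3, "n_windows": 20}],
            N=150, mu1=2.5e-3, mu2=2.5e-3, n_per_pop=4, loci_per_window=15,
        )
        w = windowed_stats(land.table, land.pop1, land.pop2, WindowScheme(50_000))
        se = w["fst"].std(ddof=1) / np.sqrt(len(w))
        assert abs(w["fst"].mean() - 0.3) < 4 * se

    def test_true_fst_annotation_matches_class_parameters(self):
        land = simulate_im_landscape(
            seed=8, classes=[{"m": 0.002, "n_windows": 2}], N=100, n_per_pop=2,
            loci_per_window=4,
        )
        assert np.allclose(land.windows["true_fst"], fst_equilibrium(100, 0.002))

    def test_outgroups_are_homozygous_and_present(self):
        land = simulate_im_landscape(
            seed=9, classes=[{"fst": 0.4, "n_windows": 2}], N=100, n_per_pop=2,
            loci_per_window=4,
        )
        og_idx = [land.table.samples.index(o) for o in land.outgroups]
        og_gt = land.table.gt[:, og_idx]
        assert set(np.unique(og_gt)) <= {0, 2}

    def test_recurrent_injection_biases_d4_negative(self):
        from ratemix.sitepatterns import block_sums, d4, d4_site_terms, taxon_freqs

        land = simulate_im_landscape(
            seed=10,
            classes=[{"fst": 0.5, "n_windows": 30}],
            N=150, mu1=2.5e-3, mu2=2.5e-3 * 2.0, n_per_pop=4, loci_per_window=15,
            recurrent_p=(0.05, 0.15), recurrent_c=0.5,
        )
        freqs = taxon_freqs(
            land.table,
            {"P1": land.pop1, "P2": land.pop2, "O1": ["O1"], "O2": ["O2"]},
        )
        terms = d4_site_terms(freqs, "P1", "P2", "O1", "O2")
        est = d4(block_sums(terms, ("abba", "baba"), 1_000_000))
        # faster P2 and more recurrent mutation in the distant outgroup:
        # the ABBA-BABA statistic goes negative without any gene flow
        assert est.estimate < 0
        assert est.z < -3
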