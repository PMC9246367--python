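"""D3/D4/rate-ratio estimators, polarization rules, and FST partitioning."""

import numpy as np
import pandas as pd
import pytest

from ratemix.popgen import GenotypeTable, WindowScheme, windowed_stats
from ratemix.sitepatterns import (
    background_fst,
    block_sums,
    d3,
    d3_site_terms,
    d4,
    d4_site_terms,
    partition_by_fst,
    rate_ratio,
    rate_ratio_site_terms,
    taxon_freqs,
)


def freq_frame(f1, f2, fo1=None, fo2=None, pos=None):
    """Frequency table as produced by taxon_freqs, from explicit frequencies."""
    n = len(f1)
    data = {
        "chromosome": np.full(n, "c1", dtype=object),
        "pos": np.arange(n) * 100 if pos is None else np.asarray(pos),
        "f_P1": np.asarray(f1, dtype=float),
        "n_P1": np.full(n, 8),
        "f_P2": np.asarray(f2, dtype=float),
        "n_P2": np.full(n, 8),
    }
    if fo1 is not None:
        data["f_O1"] = np.asarray(fo1, dtype=float)
        data["n_O1"] = np.full(n, 2)
    if fo2 is not None:
        data["f_O2"] = np.asarray(fo2, dtype=float)
        data["n_O2"] = np.full(n, 2)
    return pd.DataFrame(data)


class TestD3:
    def test_symmetric_counts_give_zero(self):
        sums = pd.DataFrame({"block": [0, 1], "abb": [2.0, 2.0], "bab": [2.0, 2.0], "n_sites": [4, 4]})
        assert d3(sums).estimate == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        sums = pd.DataFrame({"block": [0, 1], "abb": [1.5, 1.5], "bab": [2.5, 2.5], "n_sites": [4, 4]})
        assert d3(sums).estimate == pytest.approx(-0.25)

    def test_polarization_restricted_to_fixed_outgroup(self):
        # middle site has a polymorphic outgroup and must be excluded
        freqs = freq_frame([1.0, 1.0, 0.0], [0.0, 0.0, 1.0], fo1=[0.0, 0.5, 1.0])
        terms = d3_site_terms(freqs, "P1", "P2", "O1")
        assert terms["used"].tolist() == [True, False, True]
        # site 3: outgroup fixed ALT, so derived = REF; only P1 carries it
        assert terms["abb"].iloc[2] == pytest.approx(1.0)
        assert terms["bab"].iloc[2] == pytest.approx(0.0)

    def test_antisymmetric_under_focal_swap(self, rng):
        freqs = freq_frame(rng.random(50), rng.random(50), fo1=rng.choice([0.0, 1.0], 50))
        fwd = block_sums(d3_site_terms(freqs, "P1", "P2", "O1"), ("abb", "bab"), 1000)
        rev = block_sums(d3_site_terms(freqs, "P2", "P1", "O1"), ("abb", "bab"), 1000)
        assert d3(fwd).estimate == pytest.approx(-d3(rev).estimate, abs=1e-12)

    def test_block_additivity(self, rng):
        freqs = freq_frame(rng.random(40), rng.random(40), fo1=np.zeros(40))
        terms = d3_site_terms(freqs, "P1", "P2", "O1")
        pooled = block_sums(terms, ("abb", "bab"), block_size=10_000)
        fine = block_sums(terms, ("abb", "bab"), block_size=500)
        assert pooled["abb"].sum() == pytest.approx(fine["abb"].sum())
        assert d3(pooled).estimate == pytest.approx(d3(fine).estimate)

    def test_bounded_in_unit_interval(self, rng):
        freqs = freq_frame(rng.random(30), rng.random(30), fo1=np.zeros(30))
        est = d3(block_sums(d3_site_terms(freqs, "P1", "P2", "O1"), ("abb", "bab"), 1000))
        assert -1.0 <= est.estimate <= 1.0


class TestD4:
    def test_direct_arithmetic(self):
        sums = pd.DataFrame(
            {"block": [0, 1], "abba": [10.0, 15.0], "baba": [30.0, 45.0], "n_sites": [40, 60]}
        )
        assert d4(sums).estimate == pytest.approx(-0.5)

    def test_second_outgroup_gates_polarization(self):
        freqs = freq_frame([0.0, 0.0], [1.0, 1.0], fo1=[1.0, 1.0], fo2=[0.0, 0.5])
        terms = d4_site_terms(freqs, "P1", "P2", "O1", "O2")
        assert terms["used"].tolist() == [True, False]
        # P2 and O1 share the derived allele relative to O2: an ABBA site
        assert terms["abba"].iloc[0] == pytest.approx(1.0)
        assert terms["baba"].iloc[0] == pytest.approx(0.0)

    def test_antisymmetric_under_focal_swap(self, rng):
        freqs = freq_frame(
            rng.random(50), rng.random(50), fo1=rng.random(50), fo2=rng.choice([0.0, 1.0], 50)
        )
        fwd = block_sums(d4_site_terms(freqs, "P1", "P2", "O1", "O2"), ("abba", "baba"), 1000)
        rev = block_sums(d4_site_terms(freqs, "P2", "P1", "O1", "O2"), ("abba", "baba"), 1000)
        assert d4(fwd).estimate == pytest.approx(-d4(rev).estimate, abs=1e-12)


class TestRateRatio:
    def test_two_site_example(self):
        freqs = freq_frame([0.5, 0.0], [0.0, 1.0], fo1=[0.0, 0.0], fo2=[0.0, 0.0])
        sums = block_sums(
            rate_ratio_site_terms(freqs, "P1", "P2", ["O1", "O2"]), ("rr_num", "rr_den"), 1000
        )
        assert rate_ratio(sums).estimate == pytest.approx(0.5)

    def test_focal_swap_inverts_ratio(self, rng):
        freqs = freq_frame(rng.random(60), rng.random(60), fo1=np.zeros(60), fo2=np.zeros(60))
        fwd = block_sums(rate_ratio_site_terms(freqs, "P1", "P2", ["O1", "O2"]), ("rr_num", "rr_den"), 1000)
        rev = block_sums(rate_ratio_site_terms(freqs, "P2", "P1", ["O1", "O2"]), ("rr_num", "rr_den"), 1000)
        assert rate_ratio(fwd).estimate == pytest.approx(1.0 / rate_ratio(rev).estimate)

    def test_outgroup_disagreement_excludes_site(self):
        freqs = freq_frame([0.5, 0.5], [0.2, 0.2], fo1=[0.0, 0.0], fo2=[0.0, 1.0])
        terms = rate_ratio_site_terms(freqs, "P1", "P2", ["O1", "O2"])
        assert terms["used"].tolist() == [True, False]

    def test_zero_denominator_flagged(self):
        freqs = freq_frame([0.5, 0.5], [0.0, 0.0], fo1=[0.0, 0.0])
        sums = block_sums(rate_ratio_site_terms(freqs, "P1", "P2", ["O1"]), ("rr_num", "rr_den"), 1000)
        assert np.isnan(rate_ratio(sums).estimate)

    def test_sampled_allele_mode_agrees_in_expectation(self, rng):
        n = 4000
        freqs = freq_frame(rng.random(n), rng.random(n), fo1=np.zeros(n))
        analytic = rate_ratio(
            block_sums(rate_ratio_site_terms(freqs, "P1", "P2", ["O1"]), ("rr_num", "rr_den"), 1e5)
        )
        sampled = rate_ratio(
            block_sums(
                rate_ratio_site_terms(freqs, "P1", "P2", ["O1"], rng=rng), ("rr_num", "rr_den"), 1e5
            )
        )
        assert sampled.estimate == pytest.approx(analytic.estimate, rel=0.1)


class TestTaxonFreqs:
    def test_frequencies_from_called_alleles(self):
        gt = np.array([[0, 2, -1], [1, 1, 1]], dtype=np.int8)
        table = GenotypeTable(
            np.array(["c1", "c1"], dtype=object), np.array([0, 10]), gt, ["s1", "s2", "s3"]
        )
        freqs = taxon_freqs(table, {"A": ["s1", "s2"], "B": ["s3"]})
        assert freqs["f_A"].tolist() == [0.5, 0.5]
        assert np.isnan(freqs["f_B"].iloc[0])
        assert freqs["n_B"].tolist() == [0, 2]


class TestFstPartitioning:
    def make_windows(self, rng, length=10_000, width=2_000, step=500):
        n_sites, n_dip = 400, 4
        gt_a = rng.integers(0, 3, size=(n_sites, n_dip)).astype(np.int8)
        gt_b = rng.integers(0, 3, size=(n_sites, n_dip)).astype(np.int8)
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        samples = [f"a{i}" for i in range(n_dip)] + [f"b{i}" for i in range(n_dip)]
        table = GenotypeTable(
            np.full(n_sites, "c1", dtype=object), pos, np.hstack([gt_a, gt_b]),
            samples, {"c1": length},
        )
        wstats = windowed_stats(table, samples[:n_dip], samples[n_dip:], WindowScheme(width, step))
        return pos, wstats

    def test_background_matches_brute_force(self, rng):
        pos, wstats = self.make_windows(rng)
        bg = background_fst(np.full(len(pos), "c1"), pos, wstats)
        for i in rng.choice(len(pos), size=60, replace=False):
            cover = wstats[(wstats["start"] <= pos[i]) & (pos[i] < wstats["end"])]
            vals = cover["fst"].dropna()
            if len(vals):
                assert bg[i] == pytest.approx(vals.mean(), abs=1e-12)
            else:
                assert np.isnan(bg[i])

    def test_max_combine_matches_brute_force(self, rng):
        pos, wstats = self.make_windows(rng)
        bg = background_fst(np.full(len(pos), "c1"), pos, wstats, combine="max")
        for i in rng.choice(len(pos), size=40, replace=False):
            cover = wstats[(wstats["start"] <= pos[i]) & (pos[i] < wstats["end"])]
            vals = cover["fst"].dropna()
            if len(vals):
                assert bg[i] == pytest.approx(vals.max(), abs=1e-12)

    def test_threshold_zero_retains_all_covered_sites(self, rng):
        pos, wstats = self.make_windows(rng)
        bg = background_fst(np.full(len(pos), "c1"), pos, wstats)
        cuts = partition_by_fst(bg, "threshold", thresholds=[0.0])
        assert cuts[0.0].sum() == np.isfinite(bg).sum()

    def test_threshold_monotonicity(self, rng):
        pos, wstats = self.make_windows(rng)
        bg = background_fst(np.full(len(pos), "c1"), pos, wstats)
        cuts = partition_by_fst(bg, "threshold", thresholds=[0.0, 0.2, 0.4, 0.6])
        counts = [cuts[t].sum() for t in sorted(cuts)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_single_window_threshold_gate(self):
        wstats = pd.DataFrame(
            {"chromosome": ["c1"], "start": [0], "end": [100], "fst": [0.3]}
        )
        bg = background_fst(np.array(["c1"]), np.array([50]), wstats)
        cuts = partition_by_fst(bg, "threshold", thresholds=[0.2, 0.4])
        assert cuts[0.2][0] and not cuts[0.4][0]

    def test_bins_assign_each_site_once(self, rng):
        pos, wstats = self.make_windows(rng)
        bg = background_fst(np.full(len(pos), "c1"), pos, wstats)
        idx, edges = partition_by_fst(bg, "bins", n_bins=10)
        assert len(edges) == 11
        finite = np.isfinite(bg)
        assert np.all(idx[finite] >= 0)
        assert np.all(idx[~finite] == -1)

    def test_site_outside_all_windows_is_na(self):
        wstats = pd.DataFrame(
            {"chromosome": ["c1"], "start": [0], "end": [100], "fst": [0.3]}
        )
        bg = background_fst(np.array(["c1", "c1"]), np.array([50, 500]), wstats)
        assert np.isfinite(bg[0]) and np.isnan(bg[1])
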