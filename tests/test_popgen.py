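"""Windowed Hudson FST / DXY / pi and segment averaging."""

import numpy as np
import pandas as pd
import pytest

from ratemix.popgen import GenotypeTable, WindowScheme, segment_means, windowed_stats


def make_table(gt_a, gt_b, positions=None, chrom="c1", length=None):
    """Two-population GenotypeTable from per-population diploid dosage arrays."""
    gt_a = np.asarray(gt_a)
    gt_b = np.asarray(gt_b)
    gt = np.hstack([gt_a, gt_b]).astype(np.int8)
    n_sites = gt.shape[0]
    if positions is None:
        positions = np.arange(n_sites) * 10
    samples = [f"a{i}" for i in range(gt_a.shape[1])] + [f"b{i}" for i in range(gt_b.shape[1])]
    sizes = {chrom: length} if length else {}
    return (
        GenotypeTable(np.full(n_sites, chrom, dtype=object), positions, gt, samples, sizes),
        [s for s in samples if s.startswith("a")],
        [s for s in samples if s.startswith("b")],
    )


def brute_force_window(gt_a, gt_b, span):
    """Independent per-site evaluation of the Hudson estimator and diversity."""
    num = den = dxy = pia = pib = 0.0
    for i in range(gt_a.shape[0]):
        ca = [g for g in gt_a[i] if g >= 0]
        cb = [g for g in gt_b[i] if g >= 0]
        na, nb = 2 * len(ca), 2 * len(cb)
        pa, pb = sum(ca) / na, sum(cb) / nb
        d = pa * (1 - pb) + pb * (1 - pa)
        dxy += d
        pia += 2 * pa * (1 - pa) * na / (na - 1)
        pib += 2 * pb * (1 - pb) * nb / (nb - 1)
        num += (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
        den += d
    fst = num / den if den > 0 else float("nan")
    return fst, dxy / span, pia / span, pib / span


class TestWindowScheme:
    def test_sliding_windows_tile_with_partial_terminal(self):
        wins = WindowScheme(50, 10).windows(95)
        assert wins[0].tolist() == [0, 50]
        assert wins[-1].tolist() == [90, 95]
        assert np.all(wins[:, 0] < wins[:, 1])

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            WindowScheme(0)
        with pytest.raises(ValueError):
            WindowScheme(50, -1)


class TestWindowedStats:
    def test_identical_frequencies_give_zero_fst(self):
        gt = np.array([[0, 1], [1, 1], [2, 0], [1, 1]])
        table, a, b = make_table(gt, gt, length=100)
        out = windowed_stats(table, a, b, WindowScheme(100))
        assert out["fst"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_give_fst_one(self):
        n = 4
        table, a, b = make_table(np.zeros((n, 2)), np.full((n, 2), 2), length=100)
        out = windowed_stats(table, a, b, WindowScheme(100))
        assert out["fst"].iloc[0] == pytest.approx(1.0)
        assert out["dxy"].iloc[0] == pytest.approx(n / 100)
        assert out["pi_a"].iloc[0] == 0.0 and out["pi_b"].iloc[0] == 0.0

    def test_hand_set_genotypes_match_direct_estimator(self):
        gt_a = np.array([[0, 1], [2, 2], [1, 0], [1, 2]])
        gt_b = np.array([[2, 2], [0, 1], [0, 0], [2, 1]])
        table, a, b = make_table(gt_a, gt_b, length=50)
        out = windowed_stats(table, a, b, WindowScheme(50))
        fst, dxy, pia, pib = brute_force_window(gt_a, gt_b, 50)
        assert out["fst"].iloc[0] == pytest.approx(fst, abs=1e-12)
        assert out["dxy"].iloc[0] == pytest.approx(dxy, abs=1e-12)
        assert out["pi_a"].iloc[0] == pytest.approx(pia, abs=1e-12)
        assert out["pi_b"].iloc[0] == pytest.approx(pib, abs=1e-12)

    def test_agrees_with_brute_force_on_simulated_data(self, rng):
        # random genotypes incl. missing calls, sliding windows
        n_sites, n_dip = 300, 5
        gt_a = rng.integers(0, 3, size=(n_sites, n_dip))
        gt_b = rng.integers(0, 3, size=(n_sites, n_dip))
        miss = rng.random((n_sites, n_dip)) < 0.1
        gt_a[miss] = -1
        pos = np.sort(rng.choice(10_000, size=n_sites, replace=False))
        table, a, b = make_table(gt_a, gt_b, positions=pos, length=10_000)
        scheme = WindowScheme(2_000, 500)
        out = windowed_stats(table, a, b, scheme)
        for _, row in out.iterrows():
            sel = (pos >= row["start"]) & (pos < row["end"])
            # brute force needs every site called in both pops for pi terms;
            # restrict to windows where that holds for a strict comparison
            sub_a, sub_b = gt_a[sel], gt_b[sel]
            if sub_a.size == 0:
                assert row["n_sites"] == 0 and np.isnan(row["fst"])
                continue
            if np.any((sub_a >= 0).sum(axis=1) < 1) or np.any((sub_a >= 0).sum(axis=1) * 2 < 2):
                continue
            fst, dxy, pia, pib = brute_force_window(sub_a, sub_b, row["end"] - row["start"])
            if np.isfinite(fst):
                assert row["fst"] == pytest.approx(min(max(fst, 0.0), 1.0), abs=1e-12)
            assert row["dxy"] == pytest.approx(dxy, abs=1e-12)
            assert row["pi_a"] == pytest.approx(pia, abs=1e-12)

    def test_monomorphic_window_has_undefined_fst(self):
        table, a, b = make_table(np.zeros((3, 2)), np.zeros((3, 2)), length=100)
        out = windowed_stats(table, a, b, WindowScheme(100))
        assert np.isnan(out["fst"].iloc[0])
        assert out["n_sites"].iloc[0] == 3

    def test_unknown_chromosome_errors(self):
        table, a, b = make_table(np.zeros((3, 2)), np.ones((3, 2)))
        with pytest.raises(KeyError):
            windowed_stats(table, a, b, WindowScheme(100), chroms=["nope"])

    def test_empty_population_rejected(self):
        table, a, b = make_table(np.zeros((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            windowed_stats(table, [], b, WindowScheme(100))

    def test_accessibility_mask_normalization(self):
        table, a, b = make_table(np.zeros((4, 2)), np.full((4, 2), 2), length=100)
        out = windowed_stats(
            table, a, b, WindowScheme(100), accessible={"c1": np.array([[0, 40]])}
        )
        assert out["dxy"].iloc[0] == pytest.approx(4 / 40)


class TestSegmentMeans:
    def windows_frame(self, values, chrom="c1"):
        n = len(values)
        return pd.DataFrame(
            {
                "chromosome": chrom,
                "start": np.arange(n) * 10,
                "end": (np.arange(n) + 1) * 10,
                "n_sites": 5,
                "fst": values,
            }
        )

    def test_equal_partition_arithmetic(self):
        out = segment_means(self.windows_frame(np.arange(1.0, 11.0)), 2)
        assert out["fst"].tolist() == [3.0, 8.0]

    def test_single_segment_equals_chromosome_mean(self):
        vals = np.array([2.0, 4.0, 9.0])
        out = segment_means(self.windows_frame(vals), 1)
        assert out["fst"].iloc[0] == pytest.approx(vals.mean())

    def test_constant_value_preserved(self):
        out = segment_means(self.windows_frame(np.full(10, 0.42)), 5)
        assert np.allclose(out["fst"], 0.42)

    def test_invariant_to_window_order(self, rng):
        frame = self.windows_frame(rng.random(12))
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = segment_means(frame, 4)
        b = segment_means(shuffled, 4)
        pd.testing.assert_frame_equal(a, b)

    def test_oversegmentation_flags_empty_segments(self):
        out = segment_means(self.windows_frame([1.0, 2.0]), 5)
        assert (out["n_windows"] == 0).sum() > 0
        assert out.loc[out["n_windows"] == 0, "fst"].isna().all()

    def test_nan_windows_ignored_in_means(self):
        vals = np.array([1.0, np.nan, 3.0, np.nan, 5.0, np.nan, 7.0, np.nan, 9.0, np.nan])
        out = segment_means(self.windows_frame(vals), 2)
        assert out["fst"].tolist() == [3.0, 8.0]
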