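#!/usr/bin/env python
"""Observed rate ratio versus FST, and recovery of the true rate ratio r0.

Simulates the full landscape at r0 = 1.837, partitions polarizable SNPs by
ten bins of background FST, estimates the observed rate ratio r per bin with
1 Mb block-jackknife errors, and fits the single-parameter equilibrium curve

    r(FST; r0) = (1 + r0 + FST (r0 - 1)) / (1 + r0 - FST (r0 - 1))

by weighted least squares.  A stepping-stone variant with strong
within-species structure is run for contrast: structure inflates FST without
adding rate divergence, so (r - 1)/(r0 - 1) falls below FST there.
"""

from ratemix import io as rio
from ratemix import pipeline
from ratemix.simulate import simulate_im_landscape, stepping_stone_r_fst

SEED = 33
R0_TRUE = 1.837
OUT = "results"


def main() -> None:
    land = simulate_im_landscape(seed=SEED, mu1=2.5e-3, mu2=2.5e-3 * R0_TRUE)
    stats = pipeline.cmd_stats(
        {
            "table": land.table,
            "pop_a": land.pop1,
            "pop_b": land.pop2,
            "window_width": 50_000,
            "window_step": 10_000,
        }
    )
    dstats = pipeline.cmd_dstats(
        {
            "table": land.table,
            "taxa": {
                "p1": land.pop1,
                "p2": land.pop2,
                "outgroups": {"O1": ["O1"], "O2": ["O2"]},
            },
            "windows_frame": stats["windows"],
            "n_bins": 10,
            "outdir": OUT,
        }
    )
    bins = dstats["rate_ratio_bins"]
    print("observed rate ratio by FST bin:")
    for _, row in bins.iterrows():
        print(
            f"  FST ~ {row['fst_mean']:.2f}: r = {row['r']:.3f} "
            f"+/- {row['se']:.3f} (n = {row['n_sites']})"
        )
    fit = pipeline.cmd_ratefit({"bins_frame": bins, "seed": SEED, "outdir": OUT})["fit"]
    err = abs(fit.r0_hat - R0_TRUE) / R0_TRUE
    print(
        f"found: fitted r0 = {fit.r0_hat:.3f} (SE {fit.se:.3f}) vs truth "
        f"{R0_TRUE} — {100 * err:.1f}% off"
    )

    ss = stepping_stone_r_fst(
        50_000, 4, 100, m_within=0.001, m_between=0.01,
        mu1=1e-3, mu2=R0_TRUE * 1e-3, seed=SEED + 1,
    )
    remaining = (ss["r"] - 1.0) / (R0_TRUE - 1.0)
    print(
        "stepping-stone contrast (strong within-species structure): "
        f"FST = {ss['fst']:.3f} but (r-1)/(r0-1) = {remaining:.3f} — "
        "within-species structure makes the rate divergence look weaker than FST suggests"
    )
    rio.write_table(
        bins.assign(fitted_r0=fit.r0_hat), f"{OUT}/03_rate_fst_bins.tsv", meta={"seed": SEED}
    )


if __name__ == "__main__":
    main()
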