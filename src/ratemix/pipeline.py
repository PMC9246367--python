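"""Pipeline commands tying the stages into the three analyses:

* ``cmd_stats``   windowed/segment FST, DXY, pi between the pure populations
* ``cmd_entropy`` per-segment ancestry entropy (Sw, Sb) and its correlation
                  with the divergence statistics
* ``cmd_dstats``  D3/D4 over background-FST thresholds and site classes, and
                  the observed rate ratio per FST bin
* ``cmd_ratefit`` fit of the equilibrium r-FST curve, estimating r0
* ``cmd_simulate`` front-end to the synthetic-data generators

Each command is a pure function of (inputs, config, seed): reruns write
byte-identical outputs.  Configs are plain mappings (usually loaded from
YAML); every output table carries the tool version, a config hash, and the
seed in '#' header lines.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import entropy as ent
from . import io as rio
from . import sitepatterns as sp
from .jackknife import DEFAULT_BLOCK_SIZE, correlate_with_jackknife
from .popgen import GenotypeTable, WindowScheme, segment_means, windowed_stats
from .theory import fit_r0, fst_equilibrium, r_from_fst

logger = logging.getLogger(__name__)

__all__ = [
    "cmd_stats",
    "cmd_entropy",
    "cmd_dstats",
    "cmd_ratefit",
    "cmd_simulate",
    "entropy_by_segment",
]


def _meta(config: Mapping, seed=None) -> dict:
    meta = {"config_hash": rio.config_hash(dict(config))}
    if seed is not None:
        meta["seed"] = seed
    return meta


def _outdir(config: Mapping) -> Path | None:
    out = config.get("outdir")
    if out is None:
        return None
    path = Path(out)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _load_table(config: Mapping) -> GenotypeTable:
    if "table" in config:  # in-memory use by the analysis drivers
        return config["table"]
    return rio.read_vcf(config["vcf"])


def _populations(config: Mapping) -> tuple[list[str], list[str]]:
    if "popmap" in config:
        popmap = rio.read_popmap(config["popmap"])
        return popmap[config["pop_a"]], popmap[config["pop_b"]]
    return list(config["pop_a"]), list(config["pop_b"])


def cmd_stats(config: Mapping) -> dict[str, pd.DataFrame]:
    """Windowed and segment-level FST/DXY/pi tables.

    Config: vcf (or table), pop_a/pop_b (names into popmap, or sample
    lists), window_width, window_step, segments_per_chromosome,
    exclude_chromosomes, outdir.
    """
    table = _load_table(config)
    pop_a, pop_b = _populations(config)
    if not pop_a or not pop_b:
        raise ValueError("both populations need at least one sample")
    scheme = WindowScheme(
        width=int(config.get("window_width", 50_000)),
        step=int(config.get("window_step", 10_000)),
    )
    chroms = [
        c
        for c in dict.fromkeys(table.chrom.tolist())
        if c not in set(config.get("exclude_chromosomes", []))
    ]
    windows = windowed_stats(table, pop_a, pop_b, scheme, chroms=chroms)
    k = int(config.get("segments_per_chromosome", 20))
    segments = segment_means(windows, k, chrom_sizes=table.chrom_sizes or None)
    logger.info("stats: %d windows, %d segments, %d sites", len(windows), len(segments), table.n_sites)
    out = _outdir(config)
    if out is not None:
        rio.write_table(windows, out / "windows.tsv", meta=_meta(config))
        rio.write_table(segments, out / "segments.tsv", meta=_meta(config))
    return {"windows": windows, "segments": segments}


def entropy_by_segment(
    dosage: pd.DataFrame,
    segments: pd.DataFrame,
    phase: str = "balanced",
) -> pd.DataFrame:
    """Sw per individual and Sb for each genomic segment of one replicate.

    ``dosage`` is a p1-scale dosage frame (chromosome, position, one column
    per individual); ``segments`` supplies chromosome/segment boundaries.
    Segments with fewer than 2 markers get NaN entropies.
    """
    individuals = [c for c in dosage.columns if c not in ("chromosome", "position")]
    rows = []
    for _, seg in segments.iterrows():
        sub = dosage[
            (dosage["chromosome"] == seg["chromosome"])
            & (dosage["position"] >= seg["seg_start"])
            & (dosage["position"] < seg["seg_end"])
        ].sort_values("position")
        row = {
            "chromosome": seg["chromosome"],
            "segment": int(seg["segment"]),
            "n_markers": len(sub),
        }
        if len(sub) >= 2:
            Z = np.vstack(
                [
                    ent.to_signal(sub[ind].to_numpy(), sub["position"].to_numpy(), phase=phase).z
                    for ind in individuals
                ]
            )
            sw = ent.within_entropy_batch(Z)
            for ind, val in zip(individuals, sw):
                row[f"sw_{ind}"] = float(val)
            row["sw_mean"] = float(sw.mean())
            row["sb"] = ent.between_entropy(Z).sb if len(individuals) >= 2 else float("nan")
        else:
            for ind in individuals:
                row[f"sw_{ind}"] = float("nan")
            row["sw_mean"] = float("nan")
            row["sb"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_entropy(config: Mapping) -> dict[str, pd.DataFrame]:
    """Per-segment entropy across replicate ancestry estimates, plus the
    correlation of entropy with pi/DXY/FST over segments.

    Config: dosages (list of replicate TSV paths, or 'dosage_frames' with
    in-memory p1-scale frames), segments (path to the cmd_stats segment
    table, or 'segments_frame'), phase, exclude_chromosomes, outdir.
    """
    if "dosage_frames" in config:
        frames = config["dosage_frames"]
    else:
        frames = [rio.read_dosage_tsv(p) for p in config["dosages"]]
    if not frames:
        raise ValueError("no dosage replicates given")
    if "segments_frame" in config:
        segments = config["segments_frame"]
    else:
        segments = rio.read_table(config["segments"])
    excl = set(config.get("exclude_chromosomes", []))
    segments = segments[~segments["chromosome"].isin(excl)].reset_index(drop=True)
    phase = config.get("phase", "balanced")

    grid = frames[0][["chromosome", "position"]]
    per_rep = []
    for rep, frame in enumerate(frames):
        if not frame[["chromosome", "position"]].equals(grid):
            raise ValueError(f"replicate {rep} has a mismatched marker grid")
        res = entropy_by_segment(frame, segments, phase=phase)
        res.insert(0, "replicate", rep)
        per_rep.append(res)
    entropy_table = pd.concat(per_rep, ignore_index=True)

    n_rep = len(frames)
    grouped = entropy_table.groupby(["chromosome", "segment"], sort=False)
    summary = grouped[["sw_mean", "sb"]].mean().reset_index()
    if n_rep > 1:
        spread = grouped[["sw_mean", "sb"]].std(ddof=1) / np.sqrt(n_rep)
        summary["sw_mean_se"] = spread["sw_mean"].to_numpy()
        summary["sb_se"] = spread["sb"].to_numpy()
    else:
        summary["sw_mean_se"] = np.nan
        summary["sb_se"] = np.nan

    merged = summary.merge(segments, on=["chromosome", "segment"], how="inner")
    corr_rows = []
    for metric in ("sw_mean", "sb"):
        for stat in ("pi_mean", "dxy", "fst"):
            if stat not in merged.columns:
                continue
            est = correlate_with_jackknife(merged[metric], merged[stat])
            corr_rows.append(
                {
                    "entropy_metric": metric,
                    "statistic": stat,
                    "rho": est.estimate,
                    "se": est.se,
                    "z": est.z,
                    "n_segments": est.n_blocks,
                }
            )
    correlations = pd.DataFrame(corr_rows)
    out = _outdir(config)
    if out is not None:
        rio.write_table(entropy_table, out / "entropy.tsv", meta=_meta(config))
        rio.write_table(summary, out / "entropy_summary.tsv", meta=_meta(config))
        rio.write_table(correlations, out / "entropy_correlations.tsv", meta=_meta(config))
    return {"entropy": entropy_table, "summary": summary, "correlations": correlations}


def cmd_dstats(config: Mapping) -> dict[str, pd.DataFrame]:
    """D3 per outgroup, D4 per outgroup pair, and r per FST bin.

    Config: vcf (or table), taxa {p1:, p2:, outgroups: {name: samples}},
    windows (path to cmd_stats window table, or 'windows_frame'),
    fst_thresholds, n_bins, site_classes {label: BED path} (optional),
    block_size, rate_ratio_outgroups, background_combine, outdir.
    """
    table = _load_table(config)
    taxa = config["taxa"]
    groups = {"P1": taxa["p1"], "P2": taxa["p2"], **taxa["outgroups"]}
    freqs = sp.taxon_freqs(table, groups)
    og_names = list(taxa["outgroups"])
    block_size = int(config.get("block_size", DEFAULT_BLOCK_SIZE))

    if "windows_frame" in config:
        windows = config["windows_frame"]
    else:
        windows = rio.read_table(config["windows"])
    bg = sp.background_fst(
        freqs["chromosome"].to_numpy(),
        freqs["pos"].to_numpy(),
        windows,
        combine=config.get("background_combine", "mean"),
    )

    classes = {"all": np.ones(len(freqs), dtype=bool)}
    for label, bed in config.get("site_classes", {}).items():
        intervals = bed if isinstance(bed, pd.DataFrame) else rio.read_bed(bed)
        classes[label] = rio.sites_in_intervals(
            freqs["chromosome"].to_numpy(), freqs["pos"].to_numpy(), intervals
        )

    thresholds = config.get("fst_thresholds", [round(0.1 * i, 1) for i in range(9)])
    cuts = sp.partition_by_fst(bg, "threshold", thresholds=thresholds)
    min_sites = int(config.get("min_sites", 100))

    d3_rows = []
    for og in og_names:
        terms = sp.d3_site_terms(freqs, "P1", "P2", og)
        for label, cls_mask in classes.items():
            for t, mask in cuts.items():
                sums = sp.block_sums(terms, ("abb", "bab"), block_size, mask & cls_mask)
                est = sp.d3(sums)
                d3_rows.append(
                    {
                        "outgroup": og,
                        "site_class": label,
                        "fst_threshold": t,
                        "n_sites": int(sums["n_sites"].sum()) if len(sums) else 0,
                        "d3": est.estimate,
                        "se": est.se,
                        "z": est.z,
                        "low_sites": bool((sums["n_sites"].sum() if len(sums) else 0) < min_sites),
                    }
                )
    d4_rows = []
    for i, o1 in enumerate(og_names):
        for o2 in og_names[i + 1 :]:
            terms = sp.d4_site_terms(freqs, "P1", "P2", o1, o2)
            for label, cls_mask in classes.items():
                for t, mask in cuts.items():
                    sums = sp.block_sums(terms, ("abba", "baba"), block_size, mask & cls_mask)
                    est = sp.d4(sums)
                    d4_rows.append(
                        {
                            "outgroup1": o1,
                            "outgroup2": o2,
                            "site_class": label,
                            "fst_threshold": t,
                            "n_sites": int(sums["n_sites"].sum()) if len(sums) else 0,
                            "d4": est.estimate,
                            "se": est.se,
                            "z": est.z,
                        }
                    )

    # observed rate ratio r = <n2>/<n1> per FST bin (numerator: P2-exclusive)
    rr_ogs = config.get("rate_ratio_outgroups", og_names)
    rr_terms = sp.rate_ratio_site_terms(freqs, "P2", "P1", rr_ogs)
    bin_idx, edges = sp.partition_by_fst(bg, "bins", n_bins=int(config.get("n_bins", 10)))
    rr_rows = []
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        in_bin = mask & np.isfinite(bg)
        sums = sp.block_sums(rr_terms, ("rr_num", "rr_den"), block_size, mask)
        est = sp.rate_ratio(sums)
        rr_rows.append(
            {
                "bin": b,
                "fst_low": edges[b],
                "fst_high": edges[b + 1],
                "fst_mean": float(bg[in_bin].mean()) if in_bin.any() else float("nan"),
                "n_sites": int(sums["n_sites"].sum()) if len(sums) else 0,
                "r": est.estimate,
                "se": est.se,
            }
        )
    results = {
        "d3": pd.DataFrame(d3_rows),
        "d4": pd.DataFrame(d4_rows),
        "rate_ratio_bins": pd.DataFrame(rr_rows),
    }
    out = _outdir(config)
    if out is not None:
        for name, df in results.items():
            rio.write_table(df, out / f"{name}.tsv", meta=_meta(config))
    return results


def cmd_ratefit(config: Mapping) -> dict:
    """Fit r0 from a binned (fst, r, se) table; writes report and fitted curve.

    Config: bins (path to the cmd_dstats rate_ratio_bins table, or
    'bins_frame'), min_sites, seed (bootstrap), outdir.
    """
    if "bins_frame" in config:
        bins = config["bins_frame"]
    else:
        bins = rio.read_table(config["bins"])
    min_sites = int(config.get("min_sites", 50))
    usable = bins[np.isfinite(bins["r"]) & (bins["n_sites"] >= min_sites)]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable FST bins")
    rng = np.random.default_rng(int(config.get("seed", 0)))
    fit = fit_r0(
        usable["fst_mean"].to_numpy(),
        usable["r"].to_numpy(),
        usable["se"].to_numpy() if "se" in usable else None,
        rng=rng,
    )
    report = usable[["fst_mean", "r"]].copy()
    report["fitted_r"] = fit.fitted
    report["residual"] = fit.residuals
    grid = np.linspace(0.0, 1.0, 101)
    curve = pd.DataFrame({"fst": grid, "r": r_from_fst(grid, fit.r0_hat)})
    out = _outdir(config)
    if out is not None:
        rio.write_table(report, out / "ratefit_bins.tsv", meta=_meta(config, config.get("seed")))
        rio.write_table(curve, out / "ratefit_curve.tsv", meta=_meta(config, config.get("seed")))
        summary = pd.DataFrame(
            [{"r0_hat": fit.r0_hat, "se": fit.se, "residual_norm": fit.residual_norm, "n_bins": fit.n_bins}]
        )
        rio.write_table(summary, out / "ratefit.tsv", meta=_meta(config, config.get("seed")))
    return {"fit": fit, "report": report, "curve": curve}


def cmd_simulate(config: Mapping) -> dict:
    """Dispatch to the synthetic-data generators; outputs embed the seed.

    Config: model (im_pair | im_landscape | stepping_stone | site_patterns |
    block_ancestry), seed (mandatory), model parameters, outdir.
    """
    from . import simulate as sim

    model = config.get("model")
    seed = config.get("seed")
    if seed is None:
        raise ValueError("a seed is mandatory for simulation")
    seed = int(seed)
    params = {k: v for k, v in config.items() if k not in ("model", "seed", "outdir")}
    out = _outdir(config)
    meta = _meta(config, seed)
    if model == "im_pair":
        df = sim.simulate_im_pair(seed=seed, **params)
        n, m = params["N"], params["m"]
        logger.info(
            "im_pair: closed-form FST %.4f at N=%s m=%s", fst_equilibrium(n, m), n, m
        )
        if out is not None:
            rio.write_table(df, out / "im_pair.tsv", meta=meta)
        return {"records": df}
    if model == "stepping_stone":
        df = sim.simulate_stepping_stone(seed=seed, **params)
        if out is not None:
            rio.write_table(df, out / "stepping_stone.tsv", meta=meta)
        return {"records": df}
    if model == "site_patterns":
        df = sim.simulate_site_patterns(seed=seed, **params)
        if out is not None:
            rio.write_table(df, out / "site_patterns.tsv", meta=meta)
        return {"counts": df}
    if model == "block_ancestry":
        dosage = sim.simulate_block_ancestry(seed=seed, **params)
        if out is not None:
            for rep in range(dosage.shape[0]):
                rio.write_dosage_tsv(
                    out / f"ancestry_rep{rep}.tsv",
                    np.full(dosage.shape[2], "chr1"),
                    np.arange(dosage.shape[2]),
                    dosage[rep],
                    [f"ind{j}" for j in range(dosage.shape[1])],
                    meta=meta,
                )
        return {"dosage": dosage}
    if model == "im_landscape":
        res = sim.simulate_im_landscape(seed=seed, **params)
        if out is not None:
            rio.write_vcf(res.table, out / "landscape.vcf", meta={"ratemix_seed": str(seed)})
            rio.write_table(res.windows, out / "landscape_windows.tsv", meta=meta)
        return {"landscape": res}
    raise ValueError(
        f"unknown model {model!r}; choose from im_pair, im_landscape, "
        "stepping_stone, site_patterns, block_ancestry"
    )
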