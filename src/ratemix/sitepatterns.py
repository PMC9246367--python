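"""Site-pattern asymmetry statistics: D3, D4, and the observed rate ratio.

For focal taxa P1, P2 and outgroup(s), biallelic sites are polarized by the
allele carried by the required non-polymorphic outgroup(s).  Pattern
frequencies are computed analytically from derived-allele frequencies
(equivalent to averaging over random single-allele draws per taxon, which
makes the estimators deterministic); a seeded sampled-allele mode is
provided for cross-checking.

    D3 = (sum ABB - sum BAB) / (sum ABB + sum BAB)   (O1 non-polymorphic)
    D4 = (sum ABBA - sum BABA) / (sum ABBA + sum BABA) (O2 non-polymorphic)
    r  = sum f_P1 (1 - f_P2) / sum (1 - f_P1) f_P2   (all outgroups fixed
                                                      for the same allele)

ABB counts sites whose derived allele is exclusive to P1 (only P2 and the
outgroup share an allele); ABBA counts sites where P2 and O1 share the
derived allele relative to O2.  Standard errors use the 1 Mb block
jackknife.  Equal substitution rates and no outgroup gene flow give
D3 = D4 = 0 and r = 1 in expectation; rate divergence makes D3 nonzero and,
with recurrent outgroup mutation, drives D4 away from zero as well.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .jackknife import (
    DEFAULT_BLOCK_SIZE,
    JackknifeEstimate,
    assign_blocks,
    block_jackknife,
    ratio_statistic,
)
from .popgen import GenotypeTable

__all__ = [
    "taxon_freqs",
    "d3_site_terms",
    "d4_site_terms",
    "rate_ratio_site_terms",
    "block_sums",
    "d3",
    "d4",
    "rate_ratio",
    "background_fst",
    "partition_by_fst",
]

logger = logging.getLogger(__name__)


def taxon_freqs(table: GenotypeTable, groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """ALT-allele frequency and called-allele count per taxon group per site."""
    data = {"chromosome": table.chrom, "pos": table.pos}
    for name, samples in groups.items():
        n, alt = table.allele_counts(samples)
        with np.errstate(invalid="ignore", divide="ignore"):
            data[f"f_{name}"] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        data[f"n_{name}"] = n
    return pd.DataFrame(data)


def _fixed(freqs: pd.DataFrame, taxon: str) -> np.ndarray:
    f = freqs[f"f_{taxon}"].to_numpy()
    n = freqs[f"n_{taxon}"].to_numpy()
    return (n > 0) & ((f == 0.0) | (f == 1.0))


def _derived(freqs: pd.DataFrame, taxon: str, ancestral_is_alt: np.ndarray) -> np.ndarray:
    f = freqs[f"f_{taxon}"].to_numpy()
    return np.where(ancestral_is_alt, 1.0 - f, f)


def _sample_derived(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(d.shape) < d).astype(float)


def d3_site_terms(
    freqs: pd.DataFrame,
    p1: str,
    p2: str,
    outgroup: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site ABB/BAB pattern probabilities, restricted to sites where the
    outgroup is non-polymorphic.  Pass ``rng`` for the sampled-allele mode."""
    ok = _fixed(freqs, outgroup)
    anc_alt = freqs[f"f_{outgroup}"].to_numpy() == 1.0
    d1 = _derived(freqs, p1, anc_alt)
    d2 = _derived(freqs, p2, anc_alt)
    ok &= np.isfinite(d1) & np.isfinite(d2)
    if rng is not None:
        d1, d2 = _sample_derived(np.nan_to_num(d1), rng), _sample_derived(np.nan_to_num(d2), rng)
    with np.errstate(invalid="ignore"):
        abb = np.where(ok, d1 * (1.0 - d2), 0.0)
        bab = np.where(ok, (1.0 - d1) * d2, 0.0)
    return pd.DataFrame(
        {
            "chromosome": freqs["chromosome"],
            "pos": freqs["pos"],
            "abb": abb,
            "bab": bab,
            "used": ok,
        }
    )


def d4_site_terms(
    freqs: pd.DataFrame,
    p1: str,
    p2: str,
    o1: str,
    o2: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site ABBA/BABA pattern probabilities, restricted to sites where the
    second outgroup is non-polymorphic (the first may segregate)."""
    ok = _fixed(freqs, o2) & (freqs[f"n_{o1}"].to_numpy() > 0)
    anc_alt = freqs[f"f_{o2}"].to_numpy() == 1.0
    d1 = _derived(freqs, p1, anc_alt)
    d2 = _derived(freqs, p2, anc_alt)
    do1 = _derived(freqs, o1, anc_alt)
    ok &= np.isfinite(d1) & np.isfinite(d2) & np.isfinite(do1)
    if rng is not None:
        d1 = _sample_derived(np.nan_to_num(d1), rng)
        d2 = _sample_derived(np.nan_to_num(d2), rng)
        do1 = _sample_derived(np.nan_to_num(do1), rng)
    with np.errstate(invalid="ignore"):
        abba = np.where(ok, (1.0 - d1) * d2 * do1, 0.0)
        baba = np.where(ok, d1 * (1.0 - d2) * do1, 0.0)
    return pd.DataFrame(
        {
            "chromosome": freqs["chromosome"],
            "pos": freqs["pos"],
            "abba": abba,
            "baba": baba,
            "used": ok,
        }
    )


def rate_ratio_site_terms(
    freqs: pd.DataFrame,
    p1: str,
    p2: str,
    outgroups: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site rate-ratio numerator/denominator terms.

    Sites qualify only when every listed outgroup is fixed for the same
    (ancestral) allele.  The numerator counts derived alleles exclusive to
    ``p1``; ``rate_ratio(freqs, A, B, ...)`` therefore estimates the rate of
    lineage A relative to lineage B.
    """
    if len(outgroups) == 0:
        raise ValueError("rate ratio needs at least one polarizing outgroup")
    ok = np.ones(len(freqs), dtype=bool)
    for og in outgroups:
        ok &= _fixed(freqs, og)
    f0 = freqs[f"f_{outgroups[0]}"].to_numpy()
    for og in outgroups[1:]:
        ok &= freqs[f"f_{og}"].to_numpy() == f0
    anc_alt = f0 == 1.0
    d1 = _derived(freqs, p1, anc_alt)
    d2 = _derived(freqs, p2, anc_alt)
    ok &= np.isfinite(d1) & np.isfinite(d2)
    if rng is not None:
        d1, d2 = _sample_derived(np.nan_to_num(d1), rng), _sample_derived(np.nan_to_num(d2), rng)
    with np.errstate(invalid="ignore"):
        num = np.where(ok, d1 * (1.0 - d2), 0.0)
        den = np.where(ok, (1.0 - d1) * d2, 0.0)
    return pd.DataFrame(
        {
            "chromosome": freqs["chromosome"],
            "pos": freqs["pos"],
            "rr_num": num,
            "rr_den": den,
            "used": ok,
        }
    )


def block_sums(
    terms: pd.DataFrame,
    columns: Sequence[str],
    block_size: int = DEFAULT_BLOCK_SIZE,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sum per-site pattern terms into 1 Mb blocks (block-additive counts)."""
    used = terms["used"].to_numpy().copy()
    if mask is not None:
        used &= np.asarray(mask, dtype=bool)
    sub = terms.loc[used]
    if len(sub) == 0:
        return pd.DataFrame(columns=["block", *columns, "n_sites"])
    blocks = assign_blocks(sub["chromosome"].to_numpy(), sub["pos"].to_numpy(), block_size)
    out = sub[list(columns)].groupby(blocks).sum()
    out["n_sites"] = pd.Series(np.ones(len(sub)), index=sub.index).groupby(blocks).sum().astype(int)
    out.index.name = "block"
    return out.reset_index()


def _jackknife_from_sums(sums: pd.DataFrame, cols: tuple[str, str], stat) -> JackknifeEstimate:
    if len(sums) == 0:
        return JackknifeEstimate(float("nan"), float("nan"), float("nan"), 0)
    arr = sums[list(cols)].to_numpy(dtype=float)
    if len(sums) < 2:
        est = stat(arr.sum(axis=0))
        return JackknifeEstimate(float(est), float("nan"), float("nan"), len(sums))
    return block_jackknife(arr, stat, weights=sums["n_sites"].to_numpy(dtype=float))


def d3(sums: pd.DataFrame) -> JackknifeEstimate:
    """D3 with block-jackknife SE from per-block (abb, bab) sums."""
    return _jackknife_from_sums(sums, ("abb", "bab"), ratio_statistic)


def d4(sums: pd.DataFrame) -> JackknifeEstimate:
    """D4 (ABBA-BABA) with block-jackknife SE from per-block (abba, baba) sums."""
    return _jackknife_from_sums(sums, ("abba", "baba"), ratio_statistic)


def _ratio(sums_vec: np.ndarray) -> float:
    num, den = float(sums_vec[0]), float(sums_vec[1])
    return num / den if den > 0 else float("nan")


def rate_ratio(sums: pd.DataFrame) -> JackknifeEstimate:
    """Observed rate ratio with block-jackknife SE from (rr_num, rr_den) sums."""
    return _jackknife_from_sums(sums, ("rr_num", "rr_den"), _ratio)


def background_fst(
    chrom,
    pos,
    window_stats: pd.DataFrame,
    combine: str = "mean",
) -> np.ndarray:
    """Background FST per site: aggregate of all sliding windows covering it.

    ``combine`` is "mean" (default) or "max" over covering windows; windows
    with undefined FST are ignored.  Sites covered by no window (or only by
    undefined windows) get NaN.
    """
    if combine not in ("mean", "max"):
        raise ValueError("combine must be 'mean' or 'max'")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    out = np.full(len(pos), np.nan)
    width = int((window_stats["end"] - window_stats["start"]).max())
    for c, wgrp in window_stats.groupby("chromosome", sort=False):
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        wgrp = wgrp.sort_values("start")
        starts = wgrp["start"].to_numpy()
        ends = wgrp["end"].to_numpy()
        fst = wgrp["fst"].to_numpy(dtype=float)
        p = pos[sel]
        lo = np.searchsorted(starts, p - width, side="right")
        hi = np.searchsorted(starts, p, side="right")
        if combine == "mean":
            cfst = np.concatenate([[0.0], np.nancumsum(fst)])
            ccnt = np.concatenate([[0], np.cumsum(np.isfinite(fst))])
            s = cfst[hi] - cfst[lo]
            k = ccnt[hi] - ccnt[lo]
            vals = np.where(k > 0, s / np.maximum(k, 1), np.nan)
        else:
            vals = np.full(p.shape, np.nan)
            for i in range(p.size):
                cand = fst[lo[i] : hi[i]]
                cand = cand[(ends[lo[i] : hi[i]] > p[i]) & np.isfinite(cand)]
                if cand.size:
                    vals[i] = cand.max()
        # guard against truncated terminal windows not covering the site
        inside = np.zeros(p.shape, dtype=bool)
        for i in range(p.size):
            inside[i] = np.any(ends[lo[i] : hi[i]] > p[i])
        vals = np.where(inside, vals, np.nan)
        out[sel] = vals
    n_orphans = int(np.sum(~np.isfinite(out)))
    if n_orphans:
        logger.info("%d sites outside all windows assigned NA background FST", n_orphans)
    return out


def partition_by_fst(
    bg_fst: np.ndarray,
    mode: str = "threshold",
    thresholds: Sequence[float] | None = None,
    n_bins: int = 10,
    bin_range: tuple[float, float] | None = None,
):
    """Partition sites by their background FST.

    threshold mode: returns {t: boolean mask of sites with FST >= t}
    (cumulative sets; NA sites are never retained).
    bins mode: returns (bin_index array with -1 for NA, bin_edges) using
    ``n_bins`` equal-width intervals over ``bin_range`` (default: the
    observed finite range); each site is assigned exactly once.
    """
    bg_fst = np.asarray(bg_fst, dtype=float)
    finite = np.isfinite(bg_fst)
    if mode == "threshold":
        if thresholds is None:
            raise ValueError("threshold mode requires thresholds")
        return {float(t): finite & (bg_fst >= t) for t in thresholds}
    if mode == "bins":
        if not finite.any():
            raise ValueError("no sites with defined background FST")
        if bin_range is None:
            lo, hi = float(bg_fst[finite].min()), float(bg_fst[finite].max())
        else:
            lo, hi = bin_range
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.full(bg_fst.shape, -1, dtype=int)
        idx[finite] = np.clip(np.searchsorted(edges, bg_fst[finite], side="right") - 1, 0, n_bins - 1)
        return idx, edges
    raise ValueError("mode must be 'threshold' or 'bins'")
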