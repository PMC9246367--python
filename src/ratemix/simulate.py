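"""Synthetic-data generators matching the statistical structure of the analysis.

Every generator takes an explicit seed (or numpy Generator) and is
bit-reproducible given (seed, configuration).  Time is in generations and
rates are per generation per lineage; mutation follows the infinite-site
model with no back mutation.

Generators
----------
simulate_im_pair       two-deme equilibrium IM lineage pairs: sojourns and
                       exclusive derived-allele counts (the object of the
                       r-FST theory)
simulate_stepping_stone  the same pair records on a 1-D stepping-stone chain
                       split into two species, to probe how within-species
                       structure biases the observed rate ratio
simulate_im_landscape  multi-sample genotypes in windows with heterogeneous
                       gene-flow classes plus distant outgroups, emitted as
                       a GenotypeTable (and VCF) for end-to-end pipeline runs
simulate_site_patterns three- and four-taxon pattern counts corrupted by
                       recurrent outgroup mutation (probability p_i, derived
                       conversion probability c)
simulate_block_ancestry  toy diploid local-ancestry signals: uniform marker
                       spacing, per-adjacent-marker ancestry disassociation
                       probability, block ancestry i.i.d. with mean
                       contribution q
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coalescent import (
    PairRecords,
    TreeRealization,
    branch_mutation_counts,
    pair_sojourns,
    sample_tree,
)
from .popgen import GenotypeTable
from .theory import fst_equilibrium, m_from_fst

__all__ = [
    "as_rng",
    "simulate_im_pair",
    "pair_rate_ratio",
    "im_pair_fst",
    "simulate_stepping_stone",
    "stepping_stone_r_fst",
    "simulate_site_patterns",
    "simulate_block_ancestry",
    "LandscapeResult",
    "simulate_im_landscape",
]

_START = {"between": (0, 1), "within1": (0, 0), "within2": (1, 1)}


def as_rng(seed) -> np.random.Generator:
    """Coerce a seed or Generator into a numpy Generator; seeds are mandatory."""
    if seed is None:
        raise ValueError("a seed is required for every stochastic generator")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _two_deme(N: float, m: float):
    return np.array([N, N], dtype=float), np.array([[0.0, m], [m, 0.0]])


def simulate_im_pair(
    n_loci: int,
    N: float,
    m: float,
    mu1: float,
    mu2: float,
    seed,
    sampling: str = "between",
) -> pd.DataFrame:
    """Per-locus pair records under the equilibrium two-deme IM model.

    Each locus yields the coalescence time, the per-deme sojourn of both
    lineages, and Poisson exclusive derived-allele counts n1/n2 with
    branch mean mu1 * (time in population 1) + mu2 * (time in population 2).
    ``sampling`` is "between" (one lineage per population), "within1" or
    "within2".
    """
    if min(N, m, mu1, mu2) <= 0:
        raise ValueError("N, m, mu1, mu2 must all be positive")
    if sampling not in _START:
        raise ValueError(f"sampling must be one of {sorted(_START)}")
    rng = as_rng(seed)
    sizes, mig = _two_deme(N, m)
    rec: PairRecords = pair_sojourns(n_loci, _START[sampling], sizes, mig, rng)
    mu = np.array([mu1, mu2])
    n1 = rng.poisson(rec.sojourn1 @ mu)
    n2 = rng.poisson(rec.sojourn2 @ mu)
    return pd.DataFrame(
        {
            "t_coal": rec.t_coal,
            "t1_pop1": rec.sojourn1[:, 0],
            "t1_pop2": rec.sojourn1[:, 1],
            "t2_pop1": rec.sojourn2[:, 0],
            "t2_pop2": rec.sojourn2[:, 1],
            "n1": n1,
            "n2": n2,
            "deme1": rec.start_demes[0],
            "deme2": rec.start_demes[1],
        }
    )


def pair_rate_ratio(records: pd.DataFrame) -> tuple[float, float]:
    """Monte-Carlo observed rate ratio mean(n2)/mean(n1) and its delta-method SE."""
    n1 = records["n1"].to_numpy(dtype=float)
    n2 = records["n2"].to_numpy(dtype=float)
    m1, m2 = n1.mean(), n2.mean()
    if m1 <= 0:
        return float("nan"), float("nan")
    r = m2 / m1
    L = len(records)
    var = r**2 * (n2.var(ddof=1) / m2**2 + n1.var(ddof=1) / m1**2) / L
    return float(r), float(np.sqrt(var))


def im_pair_fst(
    n_loci: int, N: float, m: float, mu1: float, mu2: float, seed
) -> tuple[float, float]:
    """Empirical FST = 1 - Hw/Hb from simulated pairwise mutation counts.

    Hw averages the within-population pair heterozygosities of both
    populations; Hb is the cross-population pair value.  The SE is a
    first-order delta-method propagation over loci.
    """
    rng = as_rng(seed)
    h = {}
    for key in ("between", "within1", "within2"):
        rec = simulate_im_pair(n_loci, N, m, mu1, mu2, rng, sampling=key)
        h[key] = (rec["n1"] + rec["n2"]).to_numpy(dtype=float)
    hb = h["between"].mean()
    hw = 0.5 * (h["within1"].mean() + h["within2"].mean())
    fst = 1.0 - hw / hb
    var_hw = (h["within1"].var(ddof=1) + h["within2"].var(ddof=1)) / 4.0 / n_loci
    var_hb = h["between"].var(ddof=1) / n_loci
    var = (hw / hb) ** 2 * (var_hw / hw**2 + var_hb / hb**2)
    return float(fst), float(np.sqrt(var))


def _stepping_stone_system(
    n_demes: int,
    N: float,
    m_within: float,
    m_between: float,
    boundary: int,
    mu1: float,
    mu2: float,
):
    if n_demes < 2:
        raise ValueError("need at least 2 demes")
    if not 0 < boundary < n_demes:
        raise ValueError("boundary must split the chain into two non-empty species")
    if min(m_within, m_between) <= 0:
        raise ValueError("migration rates must be positive (connected chain)")
    mig = np.zeros((n_demes, n_demes))
    for d in range(n_demes - 1):
        rate = m_between if d == boundary - 1 else m_within
        mig[d, d + 1] = rate
        mig[d + 1, d] = rate
    sizes = np.full(n_demes, float(N))
    mu = np.where(np.arange(n_demes) < boundary, mu1, mu2)
    return sizes, mig, mu


def simulate_stepping_stone(
    n_loci: int,
    n_demes: int,
    N: float,
    m_within: float,
    m_between: float,
    mu1: float,
    mu2: float,
    seed,
    boundary: int | None = None,
    sample_demes: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Pair records on a 1-D stepping-stone chain partitioned into two species.

    Demes [0, boundary) belong to species 1 (rate mu1), the rest to species 2
    (rate mu2); adjacent demes exchange migrants at ``m_within`` except
    across the species boundary, where the rate is ``m_between``.  With
    n_demes = 2 this reduces to :func:`simulate_im_pair`.  Default sampling
    takes one lineage from each end of the chain.
    """
    boundary = n_demes // 2 if boundary is None else boundary
    sizes, mig, mu = _stepping_stone_system(n_demes, N, m_within, m_between, boundary, mu1, mu2)
    if sample_demes is None:
        sample_demes = (0, n_demes - 1)
    rng = as_rng(seed)
    rec = pair_sojourns(n_loci, sample_demes, sizes, mig, rng)
    n1 = rng.poisson(rec.sojourn1 @ mu)
    n2 = rng.poisson(rec.sojourn2 @ mu)
    return pd.DataFrame(
        {
            "t_coal": rec.t_coal,
            "t1_species1": rec.sojourn1[:, :boundary].sum(axis=1),
            "t1_species2": rec.sojourn1[:, boundary:].sum(axis=1),
            "t2_species1": rec.sojourn2[:, :boundary].sum(axis=1),
            "t2_species2": rec.sojourn2[:, boundary:].sum(axis=1),
            "n1": n1,
            "n2": n2,
            "deme1": sample_demes[0],
            "deme2": sample_demes[1],
        }
    )


def stepping_stone_r_fst(
    n_loci: int,
    n_demes: int,
    N: float,
    m_within: float,
    m_between: float,
    mu1: float,
    mu2: float,
    seed,
    boundary: int | None = None,
    sample_demes: tuple[int, int] | None = None,
) -> dict:
    """Observed rate ratio and FST between end-deme samples of the two species."""
    boundary = n_demes // 2 if boundary is None else boundary
    if sample_demes is None:
        sample_demes = (0, n_demes - 1)
    sizes, mig, mu = _stepping_stone_system(n_demes, N, m_within, m_between, boundary, mu1, mu2)
    rng = as_rng(seed)
    h = {}
    counts = {}
    for key, demes in {
        "between": sample_demes,
        "within1": (sample_demes[0], sample_demes[0]),
        "within2": (sample_demes[1], sample_demes[1]),
    }.items():
        rec = pair_sojourns(n_loci, demes, sizes, mig, rng)
        n1 = rng.poisson(rec.sojourn1 @ mu)
        n2 = rng.poisson(rec.sojourn2 @ mu)
        h[key] = (n1 + n2).astype(float)
        counts[key] = (n1, n2)
    n1, n2 = counts["between"]
    r, r_se = pair_rate_ratio(pd.DataFrame({"n1": n1, "n2": n2}))
    hb = h["between"].mean()
    hw = 0.5 * (h["within1"].mean() + h["within2"].mean())
    fst = 1.0 - hw / hb
    var_hw = (h["within1"].var(ddof=1) + h["within2"].var(ddof=1)) / 4.0 / n_loci
    var_hb = h["between"].var(ddof=1) / n_loci
    fst_se = float(abs(hw / hb) * np.sqrt(var_hw / hw**2 + var_hb / hb**2))
    return {"r": r, "r_se": r_se, "fst": float(fst), "fst_se": fst_se}


def simulate_site_patterns(
    n1: int,
    n2: int,
    p1: float,
    c: float,
    seed,
    p2: float | None = None,
    n_blocks: int = 10,
) -> pd.DataFrame:
    """Site-pattern counts after recurrent outgroup mutation, in jackknife blocks.

    ``n1`` and ``n2`` are the true numbers of sites whose derived allele is
    exclusive to focal lineage 1 and 2.  Sites are distributed uniformly over
    ``n_blocks`` blocks; each site type is drawn i.i.d. with probability
    n1/(n1+n2).  In the 3-taxon model (p2 is None) the outgroup carries a
    recurrent mutation with probability p1, converting to the focal derived
    allele with probability c (flipping the pattern) and otherwise producing
    a third allele (site dropped).  With ``p2`` given, both outgroups mutate
    independently and only converted sites yield ABBA/BABA patterns.

    Returns per-block sums compatible with :func:`ratemix.sitepatterns.d3`
    (columns abb/bab) and, when ``p2`` is given, :func:`...d4` (abba/baba).
    """
    for name, v in (("p1", p1), ("c", c)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if p2 is not None and not 0.0 <= p2 <= 1.0:
        raise ValueError("p2 must be in [0, 1]")
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise ValueError("need positive total site count")
    rng = as_rng(seed)
    n = n1 + n2
    per_block = rng.multinomial(n, np.full(n_blocks, 1.0 / n_blocks))
    rows = []
    frac1 = n1 / n
    for b in range(n_blocks):
        k = int(per_block[b])
        k1 = rng.binomial(k, frac1)
        k2 = k - k1
        if p2 is None:
            # outcomes per type: keep, flip (converted), drop (third allele)
            probs = np.array([1.0 - p1, p1 * c, p1 * (1.0 - c)])
            o1 = rng.multinomial(k1, probs)
            o2 = rng.multinomial(k2, probs)
            abb = o1[0] + o2[1]
            bab = o2[0] + o1[1]
            rows.append({"block": b, "abb": abb, "bab": bab, "n_sites": int(abb + bab)})
        else:
            # joint outcomes of (O1, O2): none / convert / third allele each
            po1 = np.array([1.0 - p1, p1 * c, p1 * (1.0 - c)])
            po2 = np.array([1.0 - p2, p2 * c, p2 * (1.0 - c)])
            joint = np.outer(po1, po2).ravel()
            t1 = rng.multinomial(k1, joint).reshape(3, 3)
            t2 = rng.multinomial(k2, joint).reshape(3, 3)
            # a type-1 (derived exclusive to lineage 1) site becomes BABA if
            # O1 alone converts, ABBA if O2 alone converts; type-2 mirrors.
            abba = t1[0, 1] + t2[1, 0]
            baba = t1[1, 0] + t2[0, 1]
            rows.append({"block": b, "abba": abba, "baba": baba, "n_sites": int(abba + baba)})
    return pd.DataFrame(rows)


def simulate_block_ancestry(
    n_snps: int,
    disassociation: float,
    q: float,
    n_individuals: int,
    n_replicates: int,
    seed,
) -> np.ndarray:
    """Toy unphased diploid ancestry signals on a uniform marker grid.

    Each haploid chromosome breaks between adjacent SNPs with probability
    ``disassociation``; every resulting block draws its ancestry i.i.d.
    Bernoulli(q) (q = average contribution of parent population 1).  Two
    haploids combine into the diploid dosage {0, 1/2, 1}.

    Returns an array of shape (n_replicates, n_individuals, n_snps) of
    dosages p1.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if not 0.0 <= disassociation <= 1.0:
        raise ValueError("disassociation probability must be in [0, 1]")
    if not 0.0 <= q <= 1.0:
        raise ValueError("contribution q must be in [0, 1]")
    rng = as_rng(seed)
    shape = (n_replicates, 2 * n_individuals, n_snps)
    breaks = rng.random((shape[0], shape[1], n_snps - 1)) < disassociation
    seg = np.zeros(shape, dtype=np.int64)
    np.cumsum(breaks, axis=-1, out=seg[..., 1:])
    draws = (rng.random(shape) < q).astype(np.int8)  # ancestry per potential block
    hap = np.take_along_axis(draws, seg, axis=-1)
    dosage = (hap[:, 0::2, :] + hap[:, 1::2, :]) / 2.0
    return dosage


@dataclass
class LandscapeResult:
    """Genotypes plus ground truth from the windowed IM landscape generator."""

    table: GenotypeTable
    windows: pd.DataFrame  # chromosome, start, end, class label, m, true FST
    pop1: list[str]
    pop2: list[str]
    outgroups: list[str]
    params: dict = field(default_factory=dict)


def _default_classes():
    return [
        {"fst": 0.1, "n_windows": 30},
        {"fst": 0.25, "n_windows": 30},
        {"fst": 0.4, "n_windows": 30},
        {"fst": 0.55, "n_windows": 30},
        {"fst": 0.7, "n_windows": 30},
        {"fst": 0.85, "n_windows": 30},
    ]


def simulate_im_landscape(
    seed,
    classes: Sequence[dict] | None = None,
    N: float = 200.0,
    mu1: float = 2.5e-3,
    mu2: float = 2.5e-3,
    n_per_pop: int = 4,
    loci_per_window: int = 20,
    window_span: int = 50_000,
    outgroup_times: Sequence[float] = (4.0, 6.0),
    outgroup_mu: float | None = None,
    recurrent_p: Sequence[float] | None = None,
    recurrent_c: float = 0.5,
    chromosome: str = "chr1",
) -> LandscapeResult:
    """Windowed two-population genotypes with heterogeneous gene flow.

    Each window belongs to a class with its own migration rate (specified as
    ``m`` or as a target equilibrium ``fst``); within a window,
    ``loci_per_window`` non-recombining loci are simulated under the two-deme
    structured coalescent with per-population substitution rates (mu1, mu2).
    Outgroup lineages attach to the ingroup root at ``outgroup_times`` (units
    of 2N generations) and are emitted as homozygous diploid samples; sites
    where an outgroup carries its own derived allele are polarization-
    ineligible, exactly as in real data.  ``recurrent_p`` optionally injects
    recurrent outgroup mutations: at each polymorphic site outgroup i mutates
    with probability p_i, converting to the focal derived allele with
    probability ``recurrent_c`` (otherwise the site becomes multiallelic and
    is removed).

    Windows are laid head-to-tail on one chromosome in shuffled class order.
    """
    rng = as_rng(seed)
    if classes is None:
        classes = _default_classes()
    class_rows = []
    for ci, cl in enumerate(classes):
        m = cl["m"] if "m" in cl else m_from_fst(cl["fst"], N)
        for _ in range(int(cl["n_windows"])):
            class_rows.append((ci, m))
    rng.shuffle(class_rows)

    n_hap = 2 * n_per_pop
    lineage_demes = [0] * n_hap + [1] * n_hap
    sizes, _ = _two_deme(N, 1.0)
    mu = np.array([mu1, mu2])
    mu_anc = 0.5 * (mu1 + mu2)
    out_mu = mu_anc if outgroup_mu is None else outgroup_mu
    t_splits = [2.0 * N * t for t in outgroup_times]
    if sorted(t_splits) != list(t_splits):
        raise ValueError("outgroup times must increase with outgroup index")
    n_out = len(t_splits)
    og_names = [f"O{i + 1}" for i in range(n_out)]
    if recurrent_p is not None and len(recurrent_p) != n_out:
        raise ValueError("recurrent_p needs one probability per outgroup")

    pop1 = [f"P1_{i}" for i in range(n_per_pop)]
    pop2 = [f"P2_{i}" for i in range(n_per_pop)]
    samples = pop1 + pop2 + og_names
    locus_span = window_span // loci_per_window

    all_chrom, all_pos, all_gt = [], [], []
    win_rows = []
    for w, (ci, m) in enumerate(class_rows):
        mig = np.array([[0.0, m], [m, 0.0]])
        w_start = w * window_span
        for loc in range(loci_per_window):
            tree: TreeRealization = sample_tree(lineage_demes, sizes, mig, rng)
            counts = branch_mutation_counts(tree, mu, rng)
            desc = tree.leaf_descendants()
            hap_rows = [desc[v] for v in np.repeat(np.arange(len(counts)), counts)]
            n_ingroup_sites = len(hap_rows)
            hap = (
                np.array(hap_rows, dtype=np.int8)
                if n_ingroup_sites
                else np.zeros((0, 2 * n_hap), dtype=np.int8)
            )
            og_states = np.zeros((n_ingroup_sites, n_out), dtype=np.int8)

            # stem mutations shared by progressively larger ingroup+outgroup sets
            seg_starts = [tree.t_mrca] + t_splits[:-1]
            extra_hap, extra_og = [], []
            for i in range(n_out):
                lo = max(seg_starts[i], tree.t_mrca)
                hi = max(t_splits[i], lo)
                k = rng.poisson(mu_anc * (hi - lo))
                for _ in range(k):
                    extra_hap.append(np.ones(2 * n_hap, dtype=np.int8))
                    og = np.zeros(n_out, dtype=np.int8)
                    og[:i] = 1  # outgroups that split below this segment share it
                    extra_og.append(og)
                # outgroup external branch: derived exclusive to that outgroup
                k_ext = rng.poisson(out_mu * t_splits[i])
                for _ in range(k_ext):
                    extra_hap.append(np.zeros(2 * n_hap, dtype=np.int8))
                    og = np.zeros(n_out, dtype=np.int8)
                    og[i] = 1
                    extra_og.append(og)
            if extra_hap:
                hap = np.vstack([hap, np.array(extra_hap, dtype=np.int8)])
                og_states = np.vstack([og_states, np.array(extra_og, dtype=np.int8)])

            n_sites = hap.shape[0]
            if n_sites == 0:
                continue
            if recurrent_p is not None:
                keep = np.ones(n_sites, dtype=bool)
                informative = np.arange(min(n_ingroup_sites, n_sites))
                for i, p_i in enumerate(recurrent_p):
                    hit = informative[rng.random(informative.size) < p_i]
                    conv = rng.random(hit.size) < recurrent_c
                    og_states[hit[conv], i] = 1
                    keep[hit[~conv]] = False  # third allele: drop the site
                hap = hap[keep]
                og_states = og_states[keep]
                n_sites = hap.shape[0]
                if n_sites == 0:
                    continue
            lo_pos = w_start + loc * locus_span
            span = max(locus_span, n_sites)
            pos = lo_pos + rng.choice(span, size=n_sites, replace=False)
            order = np.argsort(pos)
            all_pos.append(pos[order])
            gt = np.hstack(
                [hap[:, 0::2] + hap[:, 1::2], 2 * og_states]
            ).astype(np.int8)
            all_gt.append(gt[order])
            all_chrom.append(np.full(n_sites, chromosome, dtype=object))
        win_rows.append(
            {
                "chromosome": chromosome,
                "start": w_start,
                "end": w_start + window_span,
                "class": ci,
                "m": m,
                "true_fst": fst_equilibrium(N, m),
            }
        )

    chrom = np.concatenate(all_chrom)
    pos = np.concatenate(all_pos)
    gt = np.vstack(all_gt)
    order = np.argsort(pos, kind="stable")
    table = GenotypeTable(
        chrom=chrom[order],
        pos=pos[order],
        gt=gt[order],
        samples=samples,
        chrom_sizes={chromosome: len(class_rows) * window_span},
    )
    windows = pd.DataFrame(win_rows).sort_values("start").reset_index(drop=True)
    return LandscapeResult(
        table=table,
        windows=windows,
        pop1=pop1,
        pop2=pop2,
        outgroups=og_names,
        params={
            "N": N,
            "mu1": mu1,
            "mu2": mu2,
            "r0": mu2 / mu1,
            "n_per_pop": n_per_pop,
            "loci_per_window": loci_per_window,
            "window_span": window_span,
        },
    )
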