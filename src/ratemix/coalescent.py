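"""Structured-coalescent simulation engines.

Two engines share the same model: haploid demes of size N_d, per-lineage
migration at rate M[d, e] from deme d to deme e, and pairwise coalescence at
rate 1/N_d between co-located lineages.  Time is in generations, backwards.
Substitutions follow the infinite-site model with a per-deme rate mu_d, so a
branch's expected mutation count is the rate-weighted sojourn of that
lineage across demes -- the mechanism by which gene flow mixes
population-specific substitution rates.

``pair_sojourns`` simulates many independent two-lineage histories at once
(vectorized Gillespie); ``sample_tree`` simulates a full genealogy of k
lineages for one non-recombining locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairRecords", "pair_sojourns", "TreeRealization", "sample_tree", "branch_mutation_counts"]

_MAX_EVENTS = 10_000_000


def _validate(N: np.ndarray, mig: np.ndarray) -> None:
    if np.any(N <= 0):
        raise ValueError("deme sizes must be positive")
    if mig.shape[0] != mig.shape[1] or mig.shape[0] != N.size:
        raise ValueError("migration matrix must be (D, D) matching deme count")
    if np.any(mig < 0) or np.any(np.diag(mig) != 0):
        raise ValueError("migration rates must be non-negative with zero diagonal")
    if N.size > 1:
        # connectivity of the migration graph (undirected reachability)
        adj = (mig + mig.T) > 0
        seen = np.zeros(N.size, dtype=bool)
        stack = [0]
        while stack:
            d = stack.pop()
            if seen[d]:
                continue
            seen[d] = True
            stack.extend(np.flatnonzero(adj[d] & ~seen).tolist())
        if not seen.all():
            raise ValueError("migration graph is disconnected")


@dataclass
class PairRecords:
    """Per-locus records of a two-lineage structured-coalescent ensemble.

    sojourn1/sojourn2 : (n_loci, D) time each lineage spent in each deme
    t_coal            : coalescence times
    start_demes       : the sampling configuration (deme of lineage 1, 2)
    """

    t_coal: np.ndarray
    sojourn1: np.ndarray
    sojourn2: np.ndarray
    start_demes: tuple[int, int]


def pair_sojourns(
    n_loci: int,
    start_demes: tuple[int, int],
    N: np.ndarray,
    mig: np.ndarray,
    rng: np.random.Generator,
) -> PairRecords:
    """Simulate n_loci independent lineage pairs until coalescence (vectorized).

    Each locus is an exchangeable draw (no recombination within the pair
    history).  Returns per-deme sojourn times for both lineages.
    """
    N = np.asarray(N, dtype=float)
    mig = np.asarray(mig, dtype=float)
    _validate(N, mig)
    D = N.size
    out_rate = mig.sum(axis=1)
    if np.any(out_rate <= 0) and D > 1:
        raise ValueError("every deme needs a positive total out-migration rate")
    cum = np.cumsum(mig, axis=1)
    cum = cum / cum[:, -1:] if D > 1 else np.ones((1, 1))

    d1 = np.full(n_loci, start_demes[0], dtype=np.int64)
    d2 = np.full(n_loci, start_demes[1], dtype=np.int64)
    s1 = np.zeros((n_loci, D))
    s2 = np.zeros((n_loci, D))
    t = np.zeros(n_loci)
    active = np.arange(n_loci)
    events = 0
    while active.size:
        a1, a2 = d1[active], d2[active]
        r1 = out_rate[a1]
        r2 = out_rate[a2]
        rc = np.where(a1 == a2, 1.0 / N[a1], 0.0)
        total = r1 + r2 + rc
        dt = rng.exponential(1.0 / total)
        np.add.at(s1, (active, a1), dt)
        np.add.at(s2, (active, a2), dt)
        t[active] += dt
        u = rng.random(active.size) * total
        mig1 = u < r1
        mig2 = (~mig1) & (u < r1 + r2)
        coal = ~(mig1 | mig2)
        if D > 1:
            if mig1.any():
                src = a1[mig1]
                v = rng.random(src.size)
                d1[active[mig1]] = (v[:, None] < cum[src]).argmax(axis=1)
            if mig2.any():
                src = a2[mig2]
                v = rng.random(src.size)
                d2[active[mig2]] = (v[:, None] < cum[src]).argmax(axis=1)
        active = active[~coal]
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError("pair simulation exceeded event budget")
    return PairRecords(t_coal=t, sojourn1=s1, sojourn2=s2, start_demes=tuple(start_demes))


@dataclass
class TreeRealization:
    """One structured-coalescent genealogy of k sampled lineages.

    parent  : (2k-1,) parent node id, -1 at the root
    time    : node times (leaves at 0)
    sojourn : (2k-1, D) per-deme sojourn of the branch above each node
    n_leaves: k
    """

    parent: np.ndarray
    time: np.ndarray
    sojourn: np.ndarray
    n_leaves: int

    @property
    def t_mrca(self) -> float:
        return float(self.time[-1])

    def leaf_descendants(self) -> np.ndarray:
        """(2k-1, k) boolean matrix of leaves below each node."""
        k = self.n_leaves
        desc = np.zeros((2 * k - 1, k), dtype=bool)
        desc[np.arange(k), np.arange(k)] = True
        for v in range(2 * k - 1):  # children precede parents by construction
            p = self.parent[v]
            if p >= 0:
                desc[p] |= desc[v]
        return desc


def sample_tree(
    lineage_demes,
    N,
    mig,
    rng: np.random.Generator,
) -> TreeRealization:
    """Simulate the genealogy of the sampled lineages for one locus."""
    N = np.asarray(N, dtype=float)
    mig = np.asarray(mig, dtype=float)
    _validate(N, mig)
    out_rate = mig.sum(axis=1)
    k = len(lineage_demes)
    if k < 2:
        raise ValueError("need at least 2 lineages")
    n_nodes = 2 * k - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    sojourn = np.zeros((n_nodes, N.size))
    node_deme = np.full(n_nodes, -1, dtype=np.int64)
    node_deme[:k] = np.asarray(lineage_demes, dtype=np.int64)

    active = list(range(k))
    next_node = k
    t = 0.0
    events = 0
    while len(active) > 1:
        demes = node_deme[active]
        counts = np.bincount(demes, minlength=N.size)
        coal_rates = counts * (counts - 1) / 2.0 / N
        mig_rates = out_rate[demes]
        total = coal_rates.sum() + mig_rates.sum()
        dt = rng.exponential(1.0 / total)
        t += dt
        sojourn[active, demes] += dt
        u = rng.random() * total
        if u < mig_rates.sum():
            # migrate one lineage, chosen proportionally to its out-rate
            c = np.cumsum(mig_rates)
            i = int(np.searchsorted(c, u))
            src = demes[i]
            dest = int(rng.choice(N.size, p=mig[src] / out_rate[src]))
            node_deme[active[i]] = dest
        else:
            u -= mig_rates.sum()
            d = int(np.searchsorted(np.cumsum(coal_rates), u))
            in_d = [v for v in active if node_deme[v] == d]
            i, j = rng.choice(len(in_d), size=2, replace=False)
            a, b = in_d[i], in_d[j]
            parent[a] = parent[b] = next_node
            time[next_node] = t
            node_deme[next_node] = d
            active.remove(a)
            active.remove(b)
            active.append(next_node)
            next_node += 1
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError("tree simulation exceeded event budget")
    return TreeRealization(parent=parent, time=time, sojourn=sojourn, n_leaves=k)


def branch_mutation_counts(tree: TreeRealization, mu, rng: np.random.Generator) -> np.ndarray:
    """Poisson mutation counts per branch with per-deme rates (infinite sites)."""
    mu = np.asarray(mu, dtype=float)
    lam = tree.sojourn @ mu
    lam[-1] = 0.0  # root has no branch above
    return rng.poisson(lam)
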