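"""Windowed and segment-level population-genetic statistics.

FST between the two focal populations is Hudson's two-population estimator,
accumulated per window as a ratio of averages (sum of per-site numerators
over sum of per-site denominators), which is robust at the small sample
sizes typical of hard-to-collect taxa.  DXY and pi are per-site averages of
raw pairwise differences, normalized by window span (or by accessible bases
when a mask is supplied), so invariant sites implicitly contribute zero.

All coordinates are 0-based, half-open.  Genotypes are diploid ALT-dosage
codes (0/1/2, -1 for missing); a site contributes to a population's
frequencies whenever that population has at least one called allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "WindowScheme",
    "windowed_stats",
    "segment_means",
]


@dataclass
class GenotypeTable:
    """Biallelic genotypes at variant sites for a cohort of diploid samples.

    chrom, pos : per-site chromosome label and 0-based position
    gt         : (n_sites, n_samples) int8 ALT-allele dosage; -1 = missing
    samples    : column names of ``gt``
    """

    chrom: np.ndarray
    pos: np.ndarray
    gt: np.ndarray
    samples: list[str]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError("gt must be (n_sites, n_samples)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def allele_counts(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (called allele count, ALT allele count) within a sample set."""
        sub = self.gt[:, self.sample_indices(names)]
        called = sub >= 0
        n = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        return n.astype(np.int64), alt.astype(np.int64)

    def alt_freq(self, names: Sequence[str]) -> np.ndarray:
        """Per-site ALT frequency from called alleles only; NaN when uncalled."""
        n, alt = self.allele_counts(names)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def chromosome_length(self, chrom: str) -> int:
        if chrom in self.chrom_sizes:
            return int(self.chrom_sizes[chrom])
        mask = self.chrom == chrom
        if not mask.any():
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(self.pos[mask].max()) + 1

    @classmethod
    def from_haplotypes(
        cls,
        chrom,
        pos,
        haplotypes: np.ndarray,
        samples: list[str] | None = None,
        chrom_sizes: dict[str, int] | None = None,
    ) -> "GenotypeTable":
        """Pair columns of a (n_sites, 2k) 0/1 haplotype matrix into k diploids."""
        hap = np.asarray(haplotypes)
        if hap.shape[1] % 2:
            raise ValueError("haplotype matrix needs an even number of columns")
        gt = hap[:, 0::2] + hap[:, 1::2]
        if samples is None:
            samples = [f"ind{i}" for i in range(gt.shape[1])]
        return cls(chrom, pos, gt.astype(np.int8), samples, chrom_sizes or {})


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window scheme: width w, step s, left-closed right-open windows.

    Terminal partial windows are retained (truncated at chromosome length).
    """

    width: int
    step: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def stride(self) -> int:
        return self.step if self.step is not None else self.width

    def windows(self, length: int) -> np.ndarray:
        """(n, 2) array of [start, end) windows tiling [0, length)."""
        if length <= 0:
            raise ValueError("chromosome length must be positive")
        starts = np.arange(0, length, self.stride, dtype=np.int64)
        ends = np.minimum(starts + self.width, length)
        return np.column_stack([starts, ends])


def _hudson_site_terms(n_a, alt_a, n_b, alt_b):
    """Per-site Hudson numerator/denominator, dxy, and within-pop diversity.

    Sites need >= 2 called alleles in a population for its pi and for the
    FST numerator's sampling correction; dxy needs >= 1 per population.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(n_a > 0, alt_a / np.maximum(n_a, 1), np.nan)
        pb = np.where(n_b > 0, alt_b / np.maximum(n_b, 1), np.nan)
        pi_a = np.where(n_a > 1, 2.0 * pa * (1 - pa) * n_a / np.maximum(n_a - 1, 1), np.nan)
        pi_b = np.where(n_b > 1, 2.0 * pb * (1 - pb) * n_b / np.maximum(n_b - 1, 1), np.nan)
        dxy = pa * (1 - pb) + pb * (1 - pa)
        ok = (n_a > 1) & (n_b > 1)
        num = np.where(
            ok,
            (pa - pb) ** 2
            - pa * (1 - pa) / np.maximum(n_a - 1, 1)
            - pb * (1 - pb) / np.maximum(n_b - 1, 1),
            np.nan,
        )
        den = np.where(ok, dxy, np.nan)
    return num, den, dxy, pi_a, pi_b


def _nancumsum0(x: np.ndarray) -> np.ndarray:
    """Cumulative sum of nan-as-zero values, prepended with 0."""
    return np.concatenate([[0.0], np.nancumsum(x)])


def windowed_stats(
    table: GenotypeTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    scheme: WindowScheme,
    chroms: Sequence[str] | None = None,
    accessible: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-window Hudson FST, DXY, and per-population pi for two populations.

    Returns one row per window with columns chromosome, start, end, n_sites,
    fst, dxy, pi_a, pi_b, pi_mean.  Windows monomorphic in both populations
    have undefined (NaN) FST; empty windows have n_sites = 0 and NaN
    statistics.  ``accessible`` optionally maps chromosome -> (k, 2) mask
    intervals used instead of window span to normalize dxy/pi.
    """
    if len(pop_a) == 0 or len(pop_b) == 0:
        raise ValueError("each population needs at least one sample")
    n_a, alt_a = table.allele_counts(pop_a)
    n_b, alt_b = table.allele_counts(pop_b)
    num, den, dxy, pi_a, pi_b = _hudson_site_terms(n_a, alt_a, n_b, alt_b)

    if chroms is None:
        chroms = list(dict.fromkeys(table.chrom.tolist()))
    rows = []
    for chrom in chroms:
        mask = table.chrom == chrom
        pos = table.pos[mask]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        c_num = _nancumsum0(num[mask][order])
        c_den = _nancumsum0(den[mask][order])
        c_dxy = _nancumsum0(dxy[mask][order])
        c_pa = _nancumsum0(pi_a[mask][order])
        c_pb = _nancumsum0(pi_b[mask][order])
        c_cnt = np.concatenate([[0], np.arange(1, len(pos) + 1)])

        length = table.chromosome_length(chrom)
        wins = scheme.windows(length)
        lo = np.searchsorted(pos, wins[:, 0], side="left")
        hi = np.searchsorted(pos, wins[:, 1], side="left")
        n_sites = (c_cnt[hi] - c_cnt[lo]).astype(int)
        span = (wins[:, 1] - wins[:, 0]).astype(float)
        if accessible is not None and chrom in accessible:
            span = _accessible_span(np.asarray(accessible[chrom]), wins)
        s_num = c_num[hi] - c_num[lo]
        s_den = c_den[hi] - c_den[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(s_den > 0, s_num / np.where(s_den > 0, s_den, 1.0), np.nan)
            fst = np.clip(fst, 0.0, 1.0)
            dxy_w = np.where(span > 0, (c_dxy[hi] - c_dxy[lo]) / np.maximum(span, 1), np.nan)
            pa_w = np.where(span > 0, (c_pa[hi] - c_pa[lo]) / np.maximum(span, 1), np.nan)
            pb_w = np.where(span > 0, (c_pb[hi] - c_pb[lo]) / np.maximum(span, 1), np.nan)
        fst = np.where(n_sites > 0, fst, np.nan)
        dxy_w = np.where(n_sites > 0, dxy_w, np.where(span > 0, 0.0, np.nan))
        pa_w = np.where(n_sites > 0, pa_w, np.where(span > 0, 0.0, np.nan))
        pb_w = np.where(n_sites > 0, pb_w, np.where(span > 0, 0.0, np.nan))
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start": wins[:, 0],
                    "end": wins[:, 1],
                    "n_sites": n_sites,
                    "fst": fst,
                    "dxy": dxy_w,
                    "pi_a": pa_w,
                    "pi_b": pb_w,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["pi_mean"] = (out["pi_a"] + out["pi_b"]) / 2.0
    return out


def _accessible_span(intervals: np.ndarray, wins: np.ndarray) -> np.ndarray:
    """Accessible bp per window from sorted, non-overlapping mask intervals."""
    spans = np.zeros(len(wins))
    for i, (ws, we) in enumerate(wins):
        ov = np.minimum(intervals[:, 1], we) - np.maximum(intervals[:, 0], ws)
        spans[i] = np.clip(ov, 0, None).sum()
    return spans


def segment_means(
    stats: pd.DataFrame,
    k: int,
    value_cols: Sequence[str] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Average window statistics over k equal-length segments per chromosome.

    Windows are assigned to segments by midpoint; NaN window values are
    ignored; segments containing no windows are emitted with NaN means and
    n_windows = 0.  Invariant to the order of the input windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if value_cols is None:
        value_cols = [
            c for c in stats.columns
            if c not in ("chromosome", "start", "end", "n_sites")
            and np.issubdtype(stats[c].dtype, np.number)
        ]
    rows = []
    for chrom, grp in stats.groupby("chromosome", sort=False):
        length = (
            int(chrom_sizes[chrom])
            if chrom_sizes is not None and chrom in chrom_sizes
            else int(grp["end"].max())
        )
        mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0
        seg = np.clip((mid / length * k).astype(int), 0, k - 1)
        edges = np.linspace(0, length, k + 1)
        for s in range(k):
            sel = grp.loc[seg == s]
            row = {
                "chromosome": chrom,
                "segment": s,
                "seg_start": int(edges[s]),
                "seg_end": int(edges[s + 1]),
                "n_windows": int(len(sel)),
            }
            for col in value_cols:
                vals = sel[col].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                row[col] = float(vals.mean()) if vals.size else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
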