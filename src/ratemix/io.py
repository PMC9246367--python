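"""File formats: VCF, BED, population maps, dosage tables, TSV reports.

VCF positions are 1-based and converted to the package's 0-based half-open
convention on read; BED is consumed natively.  Multiallelic and non-SNP
records are skipped with a logged count.  All tabular outputs are
tab-separated with '#'-prefixed provenance header lines (tool version, seed,
config hash) and "NA" for missing values.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "read_bed",
    "sites_in_intervals",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_table",
    "config_hash",
]

# cyvcf2 gt_types codes: HOM_REF, HET, UNKNOWN, HOM_ALT
_GT_CODE = np.array([0, 1, -1, 2], dtype=np.int8)


def read_vcf(path, samples: Sequence[str] | None = None) -> GenotypeTable:
    """Load biallelic SNPs from a VCF into a GenotypeTable.

    Multiallelic records, indels and spanning deletions are skipped (count
    logged).  Contig lengths from the header populate ``chrom_sizes``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False, samples=list(samples) if samples else None)
    chroms, positions, rows = [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS - 1)  # to 0-based
        rows.append(_GT_CODE[np.asarray(var.gt_types)])
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records", skipped)
    sizes = {}
    for name in vcf.seqnames:
        try:
            sizes[name] = vcf.seqlens[vcf.seqnames.index(name)]
        except (AttributeError, IndexError, TypeError):
            break
    gt = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(vcf.samples)), np.int8)
    return GenotypeTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        gt=gt,
        samples=list(vcf.samples),
        chrom_sizes=sizes,
    )


def write_vcf(table: GenotypeTable, path, meta: Mapping[str, str] | None = None) -> None:
    """Write a GenotypeTable as an uncompressed diploid VCF (GT only)."""
    path = Path(path)
    code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, val in (meta or {}).items():
            fh.write(f"##{key}={val}\n")
        for chrom in dict.fromkeys(table.chrom.tolist()):
            fh.write(f"##contig=<ID={chrom},length={table.chromosome_length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            gts = "\t".join(code[int(g)] for g in table.gt[i])
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_popmap(path) -> dict[str, list[str]]:
    """Two-column sample-to-population text file -> {population: [samples]}."""
    out: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            sample, pop = parts
            out.setdefault(pop, []).append(sample)
    if not out:
        raise ValueError("population map is empty")
    return out


def read_bed(path) -> pd.DataFrame:
    """BED intervals (0-based half-open) as a DataFrame; extra columns kept as name."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append(
                {
                    "chromosome": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


def sites_in_intervals(chrom, pos, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites falling in any interval (per-chromosome searchsorted)."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    mask = np.zeros(len(pos), dtype=bool)
    for c, grp in intervals.groupby("chromosome", sort=False):
        sel = chrom == c
        if not sel.any():
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[sel][ok] < ends[idx[ok]]
        mask[np.flatnonzero(sel)[ok]] = True
    return mask


def read_dosage_tsv(path, diploid_scale: bool = True) -> pd.DataFrame:
    """Per-marker ancestry dosage table (chromosome, position, one column per
    individual).  ELAI-style diploid dosages in [0, 2] are halved to p1 in
    [0, 1] unless ``diploid_scale`` is False."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if cols[:2] != ["chromosome", "position"]:
        raise ValueError("dosage TSV must start with chromosome, position columns")
    ind_cols = cols[2:]
    if not ind_cols:
        raise ValueError("dosage TSV has no individual columns")
    if diploid_scale:
        df[ind_cols] = df[ind_cols] / 2.0
    return df


def write_dosage_tsv(path, chrom, positions, dosages: np.ndarray, individuals, meta=None) -> None:
    """Write p1 dosages as an ELAI-style diploid-scale TSV (values in [0, 2])."""
    df = pd.DataFrame({"chromosome": chrom, "position": positions})
    for j, ind in enumerate(individuals):
        df[ind] = 2.0 * np.asarray(dosages)[j]
    write_table(df, path, meta=meta)


_VOLATILE_KEYS = frozenset(
    {"outdir", "table", "windows_frame", "bins_frame", "segments_frame", "dosage_frames"}
)


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping.

    Output location and in-memory data objects are excluded so that the hash
    reflects the scientific configuration only.
    """
    import json

    clean = {k: v for k, v in config.items() if k not in _VOLATILE_KEYS}
    blob = json.dumps(clean, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    """TSV with '#'-prefixed provenance header lines; missing values as NA."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# ratemix {__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")
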