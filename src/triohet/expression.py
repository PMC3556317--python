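"""Count-matrix container, TSV/GFF3 readers and writers, RPKM and coverage.

The central object is :class:`ExpressionMatrix`: an integer gene x sample
count table plus per-sample metadata (genotype, stage, replicate) and
per-gene summed exon lengths.  All on-disk formats are tab-separated text
with a single header row; genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

GENOTYPES = ("P1", "P2", "F1")

__all__ = [
    "ExpressionMatrix",
    "RPKMMatrix",
    "compute_rpkm",
    "compute_coverage",
    "detection_summary",
    "log2_rpkm",
    "read_counts",
    "read_samples",
    "read_genes",
    "read_expression_set",
    "write_expression_set",
    "gene_lengths_from_gff3",
]


@dataclass
class ExpressionMatrix:
    """Gene-level integer counts with sample metadata and gene lengths.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers.
    samples
        DataFrame indexed by sample id with columns ``genotype``
        (one of ``P1``, ``P2``, ``F1``), ``stage`` and ``replicate``.
    gene_lengths
        Summed exon length in bp per gene (index = gene ids), all > 0.
    gene_coords
        Optional per-gene coordinates: columns ``chrom``, ``start``,
        ``end`` (1-based inclusive).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series
    gene_coords: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in ("genotype", "stage", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            miss = self.gene_lengths.index[self.gene_lengths.isna()]
            raise ValueError(f"genes without length: {list(miss[:5])}")
        if (self.gene_lengths <= 0).any():
            bad_g = self.gene_lengths.index[self.gene_lengths <= 0]
            raise ValueError(f"non-positive gene length for: {list(bad_g[:5])}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def library_sizes(self) -> pd.Series:
        """Per-sample column totals (default RPKM denominator source)."""
        return self.counts.sum(axis=0)

    def samples_for(self, genotype: str, stage: Optional[str] = None) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        mask = meta["genotype"] == genotype
        if stage is not None:
            mask &= meta["stage"].astype(str) == str(stage)
        return list(meta.index[mask])

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples.loc[list(self.counts.columns), "stage"].astype(str):
            if s not in seen:
                seen.append(s)
        return seen


@dataclass
class RPKMMatrix:
    """Reads-per-kilobase-per-million values with the totals used."""

    values: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("RPKM values must be finite")


def compute_rpkm(m: ExpressionMatrix, totals: Optional[pd.Series] = None) -> RPKMMatrix:
    """RPKM[g, s] = count[g, s] * 1e9 / (length_bp[g] * total[s]).

    ``totals`` defaults to the column sums of the count matrix.
    """
    if totals is None:
        totals = m.library_sizes()
    totals = totals.reindex(m.sample_ids)
    zero = totals.index[(totals <= 0) | totals.isna()]
    if len(zero):
        raise ValueError(f"zero or missing total for sample(s): {list(zero)}")
    lengths = m.gene_lengths.to_numpy(dtype=float)
    vals = m.counts.to_numpy(dtype=float) * 1e9
    vals /= lengths[:, None]
    vals /= totals.to_numpy(dtype=float)[None, :]
    return RPKMMatrix(
        values=pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids),
        totals=totals.astype(float),
    )


def compute_coverage(m: ExpressionMatrix, read_len_bp: int = 100) -> pd.DataFrame:
    """Per-gene, per-sample transcript coverage = reads * read_len / length."""
    if read_len_bp <= 0:
        raise ValueError("read_len_bp must be positive")
    lengths = m.gene_lengths.to_numpy(dtype=float)
    cov = m.counts.to_numpy(dtype=float) * float(read_len_bp) / lengths[:, None]
    return pd.DataFrame(cov, index=m.gene_ids, columns=m.sample_ids)


def detection_summary(m: ExpressionMatrix) -> tuple[int, int, float]:
    """(n detected, n total, fraction): detected = total count >= 1 over all samples."""
    tot = m.counts.sum(axis=1)
    detected = int((tot >= 1).sum())
    n = m.n_genes
    return detected, n, (detected / n if n else 0.0)


def log2_rpkm(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(RPKM + pseudocount), the default downstream analysis scale."""
    return np.log2(compute_rpkm(m).values + pseudocount)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"stage": str})
    df.index.name = "sample_id"
    return df


def read_genes(path: str | Path) -> pd.DataFrame:
    """genes.tsv: gene_id, chrom, start, end, length (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_expression_set(
    counts_path: str | Path,
    samples_path: str | Path,
    genes_path: str | Path,
) -> ExpressionMatrix:
    counts = read_counts(counts_path)
    samples = read_samples(samples_path)
    genes = read_genes(genes_path)
    coords = None
    if {"chrom", "start", "end"} <= set(genes.columns):
        coords = genes[["chrom", "start", "end"]]
    return ExpressionMatrix(
        counts=counts,
        samples=samples,
        gene_lengths=genes["length"],
        gene_coords=coords,
    )


def write_expression_set(
    m: ExpressionMatrix,
    counts_path: str | Path,
    samples_path: str | Path,
    genes_path: str | Path,
) -> None:
    m.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    m.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
    genes = pd.DataFrame(index=m.gene_ids)
    if m.gene_coords is not None:
        genes = m.gene_coords.copy()
    genes["length"] = m.gene_lengths
    genes.to_csv(genes_path, sep="\t", index_label="gene_id")


_GFF_ATTR = re.compile(r"(?:^|;)\s*(?:Parent|gene_id|ID)=([^;]+)")


def gene_lengths_from_gff3(path: str | Path, feature: str = "exon") -> pd.Series:
    """Sum exon spans per gene from a GFF3 file (end - start + 1, 1-based)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            mobj = _GFF_ATTR.search(parts[8])
            if mobj is None:
                continue
            gid = mobj.group(1).split(",")[0].strip()
            lengths[gid] = lengths.get(gid, 0) + (int(parts[4]) - int(parts[3]) + 1)
    if not lengths:
        raise ValueError(f"no {feature!r} features with identifiers found in {path}")
    out = pd.Series(lengths, name="length")
    out.index.name = "gene_id"
    return out
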