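"""Mapping genes into QTL marker intervals.

Coordinates are 1-based inclusive on both sides.  The default rule is
containment (gene entirely inside the interval); an "overlap" rule
(any intersection) is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["QTLInterval", "map_genes_to_intervals", "read_qtl_intervals"]

RULES = ("contained", "overlap")


@dataclass(frozen=True)
class QTLInterval:
    trait: str
    chrom: str
    start: int
    end: int
    marker_left: str = ""
    marker_right: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval {self.trait} {self.chrom}:{self.start}-{self.end}: start > end"
            )


def read_qtl_intervals(path: str | Path) -> list[QTLInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        QTLInterval(
            trait=row["trait"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            marker_left=str(row.get("marker_left", "")),
            marker_right=str(row.get("marker_right", "")),
        )
        for _, row in df.iterrows()
    ]


def map_genes_to_intervals(
    genes: pd.DataFrame,
    intervals: Sequence[QTLInterval],
    rule: str = "contained",
    gene_subset: Optional[Iterable] = None,
) -> pd.DataFrame:
    """Genes falling in QTL intervals, one row per (interval, gene) hit.

    ``genes`` needs columns chrom, start, end (1-based inclusive) indexed
    by gene id.  ``rule="contained"`` requires gene start >= interval
    start and gene end <= interval end; ``rule="overlap"`` any
    intersection.  ``gene_subset`` optionally restricts the candidates
    (e.g. to significant DG_HP).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    g = genes
    if gene_subset is not None:
        g = g.loc[g.index.intersection(list(gene_subset))]
    known = set(g["chrom"].unique()) | set(genes["chrom"].unique())
    unknown = sorted({iv.chrom for iv in intervals} - known)
    if unknown:
        raise ValueError(f"interval chromosome(s) absent from annotation: {unknown}")

    rows = []
    gs = g["start"].to_numpy()
    ge = g["end"].to_numpy()
    gc = g["chrom"].to_numpy()
    for iv in intervals:
        on_chrom = gc == iv.chrom
        if rule == "contained":
            hit = on_chrom & (gs >= iv.start) & (ge <= iv.end)
        else:
            hit = on_chrom & (gs <= iv.end) & (ge >= iv.start)
        for gid in g.index[hit]:
            rows.append(
                {
                    "trait": iv.trait,
                    "chrom": iv.chrom,
                    "interval_start": iv.start,
                    "interval_end": iv.end,
                    "marker_left": iv.marker_left,
                    "marker_right": iv.marker_right,
                    "gene_id": gid,
                    "gene_start": int(g.at[gid, "start"]),
                    "gene_end": int(g.at[gid, "end"]),
                }
            )
    cols = [
        "trait",
        "chrom",
        "interval_start",
        "interval_end",
        "marker_left",
        "marker_right",
        "gene_id",
        "gene_start",
        "gene_end",
    ]
    return pd.DataFrame(rows, columns=cols)
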