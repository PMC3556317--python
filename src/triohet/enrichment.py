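"""Hypergeometric term over-representation with BH correction."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats

from .de import adjust_fdr

__all__ = ["TermAnnotation", "enrich", "read_terms"]


@dataclass
class TermAnnotation:
    """gene -> set of term ids, with term names and namespaces."""

    gene_terms: Mapping[str, frozenset]
    term_names: Mapping[str, str] = field(default_factory=dict)
    term_namespace: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "TermAnnotation":
        """Build from a long table with columns gene_id, term[, name, namespace]."""
        gene_terms: dict[str, set] = {}
        for gid, term in zip(df["gene_id"], df["term"]):
            gene_terms.setdefault(gid, set()).add(term)
        names = {}
        namespaces = {}
        if "name" in df.columns:
            names = dict(zip(df["term"], df["name"]))
        if "namespace" in df.columns:
            namespaces = dict(zip(df["term"], df["namespace"]))
        return cls(
            gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
            term_names=names,
            term_namespace=namespaces,
        )


def read_terms(path: str | Path) -> TermAnnotation:
    return TermAnnotation.from_table(pd.read_csv(path, sep="\t"))


def enrich(
    gene_set: Iterable,
    background: Iterable,
    annotation: TermAnnotation,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail test per term.

    For each term with K background hits, a gene set of size n drawn from
    a universe of size N, and k hits in the set: p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  BH-FDR is computed within each namespace.
    Returns one row per term with k > 0: k, K, n, N, pvalue, fdr,
    significant (p <= p_max) and significant_fdr flags.
    """
    bg = set(background)
    gs = set(gene_set)
    offenders = sorted(gs - bg)
    if offenders:
        raise ValueError(f"genes in set absent from background: {offenders[:10]}")
    n, N = len(gs), len(bg)

    term_bg: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for gene in bg:
        for term in annotation.gene_terms.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in gs:
                term_hits[term] = term_hits.get(term, 0) + 1

    rows = []
    for term, k in sorted(term_hits.items()):
        K = term_bg[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, term),
                "namespace": annotation.term_namespace.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "name", "namespace", "k", "K", "n", "N", "pvalue"]
    )
    if len(out):
        out["fdr"] = 1.0
        for _, idx in out.groupby("namespace").groups.items():
            out.loc[idx, "fdr"] = adjust_fdr(out.loc[idx, "pvalue"])
        out["significant"] = out["pvalue"] <= p_max
        out["significant_fdr"] = out["fdr"] <= p_max
        out = out.sort_values("pvalue", kind="stable").reset_index(drop=True)
    return out
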