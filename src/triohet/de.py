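"""Two-group negative-binomial exact test and DEG partitioning.

Re-implements the classic conditional exact test for count data: after
equalizing library sizes, the split of a gene's total pseudo-count
between the two groups is beta-binomial under the NB null of equal
means, and the two-sided p-value sums the probabilities of all splits
no more likely than the observed one.  BH false-discovery control and
the FDR <= 0.05 & |log2FC| >= 1 DEG call sit on top, plus the partition
of DEGs into hybrid-vs-parent (DG_HP) and parent-vs-parent (DG_PP)
sets with Venn region counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .expression import ExpressionMatrix

__all__ = [
    "Contrast",
    "DEGPartition",
    "trio_contrasts",
    "equalize_library_sizes",
    "estimate_dispersion",
    "exact_nb_test",
    "adjust_fdr",
    "de_test",
    "call_degs",
    "partition_degs",
]

# contrast label -> (group A genotype, group B genotype); log2FC is B over A
CONTRAST_GENOTYPES = {"R/F": ("P1", "F1"), "X/F": ("P2", "F1"), "R/X": ("P1", "P2")}

# relative tolerance when deciding a split is "no more likely" than observed
_TIE_RTOL = 1e-9

# prior degrees of freedom pulling gene-wise dispersions to the common value
DISPERSION_PRIOR_DF = 20.0


@dataclass
class Contrast:
    """One two-group comparison at a single stage."""

    label: str
    group_a: Sequence[str]
    group_b: Sequence[str]
    stage: str

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {self.label}: each group needs >= 2 samples")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.label}: groups overlap")

    @property
    def samples(self) -> list[str]:
        return list(self.group_a) + list(self.group_b)


def trio_contrasts(m: ExpressionMatrix, stage: str) -> dict[str, Contrast]:
    """The three canonical contrasts (R/F, X/F, R/X) at one stage."""
    out = {}
    for label, (ga, gb) in CONTRAST_GENOTYPES.items():
        out[label] = Contrast(
            label=label,
            group_a=m.samples_for(ga, stage),
            group_b=m.samples_for(gb, stage),
            stage=stage,
        )
    return out


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def equalize_library_sizes(
    counts: pd.DataFrame, lib_sizes: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Scale each column to the geometric-mean library size, rounded to ints."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0]
        raise ValueError(f"zero library size for sample(s): {list(bad)}")
    target = _geometric_mean(lib)
    scaled = counts.to_numpy(dtype=float) * (target / lib)[None, :]
    return pd.DataFrame(
        np.round(scaled).astype(np.int64), index=counts.index, columns=counts.columns
    )


def _mom_phi(group: np.ndarray) -> np.ndarray:
    """Raw method-of-moments dispersion per gene for one group (genes x reps)."""
    mu = group.mean(axis=1)
    s2 = group.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (s2 - mu) / mu**2
    phi[mu == 0] = np.nan
    return phi


def estimate_dispersion(
    m: ExpressionMatrix, contrast: Contrast, prior_df: float = DISPERSION_PRIOR_DF
) -> pd.Series:
    """Shrunk gene-wise NB dispersions on library-size-normalized counts.

    Gene-wise phi is the method-of-moments value max(0, (s2 - mu) / mu^2)
    averaged over the two groups; it is pulled toward the trimmed-mean
    common dispersion with ``prior_df`` pseudo-degrees of freedom.  Genes
    with no information (all zero) get the common value.
    """
    counts = m.counts[list(contrast.samples)]
    lib = m.library_sizes()[list(contrast.samples)]
    norm = counts.to_numpy(dtype=float) / lib.to_numpy(dtype=float)[None, :]
    norm *= _geometric_mean(lib.to_numpy(dtype=float))
    na, nb = len(contrast.group_a), len(contrast.group_b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group to estimate dispersion")
    phi_a = _mom_phi(norm[:, :na])
    phi_b = _mom_phi(norm[:, na:])
    both = np.column_stack([phi_a, phi_b])
    n_obs = (~np.isnan(both)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        raw = np.where(n_obs > 0, np.nansum(both, axis=1) / np.maximum(n_obs, 1), np.nan)
    raw = np.clip(raw, 0.0, None)

    informative = ~np.isnan(raw)
    if informative.sum() == 0:
        common = 0.0
    else:
        vals = np.sort(raw[informative])
        k = int(0.1 * len(vals))
        trimmed = vals[k : len(vals) - k] if len(vals) > 2 * k else vals
        common = float(trimmed.mean())

    resid_df = na + nb - 2
    shrunk = (prior_df * common + resid_df * raw) / (prior_df + resid_df)
    shrunk[~informative] = common
    return pd.Series(shrunk, index=m.gene_ids, name="dispersion")


def _conditional_log_pmf(total: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(Y_A = a | Y_A + Y_B = total) for a = 0..total (beta-binomial)."""
    a = np.arange(total + 1, dtype=float)
    b = total - a
    logp = (
        gammaln(a + r_a)
        - gammaln(a + 1.0)
        + gammaln(b + r_b)
        - gammaln(b + 1.0)
    )
    return logp - logsumexp(logp)


def exact_nb_test_single(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional exact p for one gene's group sums.

    Under H0 (equal per-sample NB means, dispersion ``phi``), the group
    sums are NB with sizes n_a/phi and n_b/phi sharing the success
    probability, so Y_A | total is beta-binomial; phi = 0 degenerates to
    binomial(total, n_a / (n_a + n_b)).  The p-value sums P(split) over
    all splits with probability <= the observed one (small relative
    tolerance for floating-point ties).
    """
    total = int(sum_a + sum_b)
    if total == 0:
        return 1.0
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if phi == 0:
        a = np.arange(total + 1, dtype=float)
        pr = n_a / (n_a + n_b)
        logp = (
            gammaln(total + 1.0)
            - gammaln(a + 1.0)
            - gammaln(total - a + 1.0)
            + a * np.log(pr)
            + (total - a) * np.log1p(-pr)
        )
    else:
        logp = _conditional_log_pmf(total, n_a / phi, n_b / phi)
    probs = np.exp(logp - logsumexp(logp))
    obs = probs[int(sum_a)]
    return float(min(1.0, probs[probs <= obs * (1.0 + _TIE_RTOL)].sum()))


def exact_nb_test(
    counts_a: pd.DataFrame | np.ndarray,
    counts_b: pd.DataFrame | np.ndarray,
    dispersion: pd.Series | np.ndarray,
) -> np.ndarray:
    """Per-gene two-sided exact NB p-values on library-size-equalized counts."""
    ca = np.asarray(counts_a)
    cb = np.asarray(counts_b)
    if (ca < 0).any() or (cb < 0).any():
        raise ValueError("counts must be non-negative")
    phi = np.asarray(dispersion, dtype=float)
    sums_a = ca.sum(axis=1)
    sums_b = cb.sum(axis=1)
    n_a, n_b = ca.shape[1], cb.shape[1]
    return np.array(
        [
            exact_nb_test_single(int(sa), int(sb), n_a, n_b, float(ph))
            for sa, sb, ph in zip(sums_a, sums_b, phi)
        ]
    )


def adjust_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_test(
    m: ExpressionMatrix,
    contrast: Contrast,
    dispersion: Optional[pd.Series] = None,
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Full DE table for one contrast.

    Columns: mean_a, mean_b (normalized), log2fc (B over A, pseudocount
    0.5 per group mean), pvalue, fdr, is_deg.
    """
    if dispersion is None:
        dispersion = estimate_dispersion(m, contrast)
    counts = m.counts[list(contrast.samples)]
    lib = m.library_sizes()[list(contrast.samples)]
    pseudo = equalize_library_sizes(counts, lib)
    na = len(contrast.group_a)
    pa, pb = pseudo.iloc[:, :na], pseudo.iloc[:, na:]

    pvals = exact_nb_test(pa, pb, dispersion.reindex(m.gene_ids))
    mean_a = pa.mean(axis=1)
    mean_b = pb.mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
        },
        index=m.gene_ids,
    )
    out["fdr"] = adjust_fdr(out["pvalue"])
    return call_degs(out, fdr_max=fdr_max, min_abs_log2fc=min_abs_log2fc)


def call_degs(
    results: pd.DataFrame, fdr_max: float = 0.05, min_abs_log2fc: float = 1.0
) -> pd.DataFrame:
    """Flag genes with FDR <= fdr_max AND |log2FC| >= min_abs_log2fc (inclusive)."""
    out = results.copy()
    out["is_deg"] = (out["fdr"] <= fdr_max) & (out["log2fc"].abs() >= min_abs_log2fc)
    return out


@dataclass
class DEGPartition:
    """DG_HP / DG_PP split of the three per-stage contrasts."""

    stage: str
    dg_hp: frozenset
    dg_pp: frozenset
    per_contrast: dict
    venn: dict  # region key "RF,XF,RX" membership pattern -> count

    @property
    def total(self) -> int:
        return len(self.dg_hp | self.dg_pp)


def partition_degs(deg_sets: Mapping[str, Iterable], stage: str) -> DEGPartition:
    """DG_HP = (R/F) U (X/F); DG_PP = R/X; 7 Venn region counts."""
    missing = set(CONTRAST_GENOTYPES) - set(deg_sets)
    if missing:
        raise ValueError(f"missing contrast(s): {sorted(missing)}")
    rf = frozenset(deg_sets["R/F"])
    xf = frozenset(deg_sets["X/F"])
    rx = frozenset(deg_sets["R/X"])
    venn = {}
    for key, members in (
        ("100", rf - xf - rx),
        ("010", xf - rf - rx),
        ("001", rx - rf - xf),
        ("110", (rf & xf) - rx),
        ("101", (rf & rx) - xf),
        ("011", (xf & rx) - rf),
        ("111", rf & xf & rx),
    ):
        venn[key] = len(members)
    return DEGPartition(
        stage=stage,
        dg_hp=rf | xf,
        dg_pp=rx,
        per_contrast={"R/F": len(rf), "X/F": len(xf), "R/X": len(rx)},
        venn=venn,
    )
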