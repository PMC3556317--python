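"""Synthetic trio (P1, P2, F1) data with known truth.

Generates negative-binomial count matrices whose per-genotype log2 means
follow u + a (P1), u - a (P2), u + d (F1) plus a replicate block effect,
along with trait phenotypes, gene/term annotations, QTL intervals and a
per-gene truth table, so every downstream stage can be tested without
external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_expression_set
from .phenotype import TraitMeasurements, write_traits

__all__ = [
    "SimulationConfig",
    "TraitSpec",
    "simulate_trio_counts",
    "simulate_trait_measurements",
    "write_fixture_set",
    "true_pattern_class",
    "DEFAULT_TRAIT_SPECS",
]


@dataclass
class SimulationConfig:
    """Parameters of the trio count simulation.

    ``dispersion`` is either a single NB dispersion phi (variance
    mu + phi * mu^2; 0 selects the Poisson limit) or a ``(shape, scale)``
    pair for gene-wise gamma-distributed dispersions.
    """

    n_genes: int = 2000
    n_replicates: int = 2
    stages: Sequence[str] = ("tillering", "heading")
    mean_log_expression: tuple[float, float] = (5.0, 2.0)  # log2 location, scale
    additive_sd: float = 0.7
    dominance_sd: float = 0.7
    frac_null: float = 0.3
    dispersion: Union[float, tuple[float, float]] = 0.1
    library_sizes: Optional[Sequence[float]] = None  # per-sample totals
    gene_length_range: tuple[int, int] = (200, 5000)
    replicate_effect_sd: float = 0.05
    seed: int = 0
    n_chromosomes: int = 12

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1 (empty simulation refused)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.stages:
            raise ValueError("stages must be non-empty")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must lie in [0, 1]")
        loc, scale = self.mean_log_expression
        if scale < 0:
            raise ValueError("mean_log_expression scale must be >= 0")
        if isinstance(self.dispersion, tuple):
            shape, scale_d = self.dispersion
            if shape <= 0 or scale_d <= 0:
                raise ValueError("dispersion gamma parameters must be > 0")
        elif self.dispersion < 0:
            raise ValueError("dispersion must be >= 0 (0 = Poisson limit)")
        lo, hi = self.gene_length_range
        if lo < 100 or hi < lo:
            raise ValueError("gene_length_range must satisfy 100 <= lo <= hi")
        if self.additive_sd < 0 or self.dominance_sd < 0:
            raise ValueError("effect sds must be >= 0")
        if self.replicate_effect_sd < 0:
            raise ValueError("replicate_effect_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return 3 * self.n_replicates * len(self.stages)


def true_pattern_class(a: float, d: float) -> str:
    """Noiseless dominance-ratio class from true effects (log2 scale).

    Uses composite [a] = |a|: d > |a| -> AHP, d == |a| > 0 -> HPL,
    0 < d < |a| -> MPL, and symmetrically LPL / BLP for d < 0;
    d == 0 -> "none".
    """
    abs_a = abs(a)
    if d == 0:
        return "none"
    if d > 0:
        if d > abs_a:
            return "AHP"
        if d == abs_a:
            return "HPL"
        return "MPL"
    if -d > abs_a:
        return "BLP"
    if -d == abs_a:
        return "LPL"
    return "MPL"


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for stage in config.stages:
        for geno in ("P1", "P2", "F1"):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{geno}_{stage}_r{rep}",
                        "genotype": geno,
                        "stage": str(stage),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_trio_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the trio count matrix and its per-gene truth table.

    Returns ``(matrix, truth)`` where ``truth`` has per-gene columns
    ``true_a``, ``true_d``, ``true_class`` and per-contrast true DEG
    status at |log2FC| >= 1 (``true_deg_R/F`` etc.).  Deterministic for
    a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    samples = _sample_table(config)
    S = len(samples)

    loc, scale = config.mean_log_expression
    u = rng.normal(loc, scale, size=G)
    a = rng.normal(0.0, config.additive_sd, size=G) if config.additive_sd else np.zeros(G)
    d = rng.normal(0.0, config.dominance_sd, size=G) if config.dominance_sd else np.zeros(G)
    null_mask = rng.random(G) < config.frac_null
    a[null_mask] = 0.0
    d[null_mask] = 0.0

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=G)

    if isinstance(config.dispersion, tuple):
        shape, scale_d = config.dispersion
        phi = rng.gamma(shape, scale_d, size=G)
    else:
        phi = np.full(G, float(config.dispersion))

    if config.library_sizes is None:
        lib = np.full(S, 1e6)
    else:
        lib = np.asarray(config.library_sizes, dtype=float)
        if lib.shape != (S,):
            raise ValueError(
                f"library_sizes must have one entry per sample ({S}), got {lib.shape}"
            )
        if (lib <= 0).any():
            raise ValueError("library_sizes must be > 0")

    geno_effect = {"P1": a, "P2": -a, "F1": d}
    block = {
        (str(stage), rep): rng.normal(0.0, config.replicate_effect_sd)
        for stage in config.stages
        for rep in range(1, config.n_replicates + 1)
    }

    counts = np.empty((G, S), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        log2_mean = u + geno_effect[row["genotype"]] + block[(row["stage"], row["replicate"])]
        rel = np.exp2(log2_mean) * lengths  # longer genes attract more reads
        mu = rel / rel.sum() * lib[j]
        pois = phi <= 0
        col = np.empty(G, dtype=np.int64)
        if pois.any():
            col[pois] = rng.poisson(mu[pois])
        if (~pois).any():
            r = 1.0 / phi[~pois]
            p = r / (r + mu[~pois])
            col[~pois] = rng.negative_binomial(r, p)
        counts[:, j] = col

    gene_ids = pd.Index([f"g{i:05d}" for i in range(G)], name="gene_id")
    chrom_idx = np.arange(G) % config.n_chromosomes
    # lay genes end to end per chromosome with 1 kb gaps, 1-based inclusive
    coords = pd.DataFrame(index=gene_ids)
    coords["chrom"] = [f"chr{c + 1}" for c in chrom_idx]
    starts = np.zeros(G, dtype=np.int64)
    offset = np.zeros(config.n_chromosomes, dtype=np.int64)
    for i in range(G):
        c = chrom_idx[i]
        starts[i] = offset[c] + 1
        offset[c] += lengths[i] + 1000
    coords["start"] = starts
    coords["end"] = starts + lengths - 1

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples.index),
        samples=samples,
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        gene_coords=coords,
    )

    truth = pd.DataFrame(index=gene_ids)
    truth["true_u"] = u
    truth["true_a"] = a
    truth["true_d"] = d
    truth["true_class"] = [true_pattern_class(ai, di) for ai, di in zip(a, d)]
    truth["true_phi"] = phi
    # true log2 fold changes per contrast (hybrid over parent; P2 over P1)
    fc = {"R/F": d - a, "X/F": d + a, "R/X": -2.0 * a}
    for label, lfc in fc.items():
        truth[f"true_lfc_{label}"] = lfc
        truth[f"true_deg_{label}"] = np.abs(lfc) >= 1.0
    return matrix, truth


@dataclass
class TraitSpec:
    name: str
    p1_mean: float
    p2_mean: float
    f1_mean: float
    noise_sd: float = 0.0
    n_replicates: int = 10
    units: str = ""


# Genotype means printed for the study's root traits (used as defaults for
# fixture phenotypes; replicate-level raw data was never published).
DEFAULT_TRAIT_SPECS = [
    TraitSpec("root_length_tillering", 31.96, 25.58, 33.34, 1.5, 10, "cm"),
    TraitSpec("root_dry_weight_tillering", 1.45, 2.24, 3.11, 0.1, 10, "g"),
    TraitSpec("root_shoot_ratio_tillering", 0.20, 0.19, 0.25, 0.01, 10, ""),
    TraitSpec("root_length_heading", 48.63, 37.50, 64.45, 2.0, 10, "cm"),
    TraitSpec("root_dry_weight_heading", 6.44, 3.06, 11.27, 0.3, 10, "g"),
]


def simulate_trait_measurements(
    trait_specs: Sequence[TraitSpec],
    seed: int = 0,
) -> tuple[list[TraitMeasurements], pd.DataFrame]:
    """Gaussian replicate values around specified genotype means.

    Returns the measurements and a truth table with the implied true
    MPH/HPH percentages (computed from the specified means, not the
    noisy replicates).
    """
    rng = np.random.default_rng(seed)
    out: list[TraitMeasurements] = []
    rows = []
    for spec in trait_specs:
        if spec.n_replicates < 2:
            raise ValueError(
                f"trait {spec.name!r}: need >= 2 replicates (t-test undefined)"
            )
        vals = {}
        for geno, mean in (
            ("P1", spec.p1_mean),
            ("P2", spec.p2_mean),
            ("F1", spec.f1_mean),
        ):
            vals[geno] = mean + rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
        out.append(TraitMeasurements(name=spec.name, units=spec.units, values=vals))
        mp = (spec.p1_mean + spec.p2_mean) / 2.0
        hp = max(spec.p1_mean, spec.p2_mean)
        if mp == 0 or hp == 0:
            raise ValueError(f"trait {spec.name!r}: zero mid/high parent mean")
        rows.append(
            {
                "trait": spec.name,
                "true_mph": 100.0 * (spec.f1_mean - mp) / mp,
                "true_hph": 100.0 * (spec.f1_mean - hp) / hp,
            }
        )
    truth = pd.DataFrame(rows).set_index("trait")
    return out, truth


def _simulate_terms(
    gene_ids: pd.Index, n_terms: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Random gene->term annotation (each gene gets 0-3 terms)."""
    rows = []
    term_ids = [f"T{i:04d}" for i in range(n_terms)]
    for gid in gene_ids:
        for t in rng.choice(term_ids, size=rng.integers(0, 4), replace=False):
            rows.append(
                {
                    "gene_id": gid,
                    "term": t,
                    "name": f"term {t}",
                    "namespace": "biological_process",
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "term", "name", "namespace"])


def _simulate_qtl_intervals(
    coords: pd.DataFrame, rng: np.random.Generator, n_intervals: int = 6
) -> pd.DataFrame:
    """Intervals spanning random gene runs, tagged with trait labels."""
    traits = ["root_length", "root_dry_weight", "root_shoot_ratio"]
    rows = []
    by_chrom = coords.groupby("chrom", sort=False)
    chroms = list(by_chrom.groups)
    for i in range(n_intervals):
        chrom = chroms[rng.integers(0, len(chroms))]
        sub = by_chrom.get_group(chrom).sort_values("start")
        k = len(sub)
        lo = int(rng.integers(0, max(1, k - 5)))
        hi = min(k - 1, lo + int(rng.integers(2, 8)))
        rows.append(
            {
                "trait": traits[i % len(traits)],
                "chrom": chrom,
                "start": int(sub["start"].iloc[lo]),
                "end": int(sub["end"].iloc[hi]),
                "marker_left": f"RM{1000 + 2 * i}",
                "marker_right": f"RM{1001 + 2 * i}",
            }
        )
    return pd.DataFrame(rows)


def write_fixture_set(
    output_dir: str | Path,
    config: Optional[SimulationConfig] = None,
    trait_specs: Optional[Sequence[TraitSpec]] = None,
) -> dict:
    """Write the full fixture file set and return the manifest.

    Emits counts.tsv, samples.tsv, genes.tsv, terms.tsv, traits.tsv,
    qtl_intervals.tsv, truth.tsv and manifest.json; every table
    round-trips through the :mod:`triohet.expression` readers.
    """
    config = config or SimulationConfig()
    trait_specs = list(trait_specs) if trait_specs is not None else DEFAULT_TRAIT_SPECS
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_trio_counts(config)
    rng = np.random.default_rng(config.seed + 1)  # annotation stream
    terms = _simulate_terms(matrix.gene_ids, n_terms=25, rng=rng)
    qtl = _simulate_qtl_intervals(matrix.gene_coords, rng=rng)
    traits, trait_truth = simulate_trait_measurements(trait_specs, seed=config.seed + 2)

    files = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "genes": outdir / "genes.tsv",
        "terms": outdir / "terms.tsv",
        "traits": outdir / "traits.tsv",
        "qtl_intervals": outdir / "qtl_intervals.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_set(matrix, files["counts"], files["samples"], files["genes"])
    terms.to_csv(files["terms"], sep="\t", index=False)
    write_traits(traits, files["traits"])
    qtl.to_csv(files["qtl_intervals"], sep="\t", index=False)
    truth.to_csv(files["truth"], sep="\t", index_label="gene_id")

    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "files": {k: str(v.name) for k, v in files.items()},
        "sha256": {
            k: hashlib.sha256(v.read_bytes()).hexdigest() for k, v in files.items()
        },
        "trait_truth": trait_truth.round(10).to_dict(orient="index"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
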