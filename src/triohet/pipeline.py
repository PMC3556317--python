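"""End-to-end pipeline: normalize -> DE -> classify -> summarize -> extras.

A :class:`PipelineConfig` (typically loaded from YAML) names the input
tables and thresholds; :func:`run_pipeline` executes every applicable
stage, writes TSV outputs into the configured directory and returns a
manifest with input checksums and per-stage row counts.  Each stage is a
pure function of its inputs and the config, so identical inputs + seed
give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_samples
from .de import de_test, estimate_dispersion, partition_degs, trio_contrasts
from .dominance import classify_hp, fit_trio_anova, summarize_patterns
from .enrichment import enrich, read_terms
from .expression import (
    compute_rpkm,
    detection_summary,
    log2_rpkm,
    read_expression_set,
)
from .phenotype import heterosis_table, read_traits
from .qtl import map_genes_to_intervals, read_qtl_intervals
from .simulate import SimulationConfig, write_fixture_set

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    output_dir: str = "triohet_out"
    counts: Optional[str] = None
    samples: Optional[str] = None
    genes: Optional[str] = None
    terms: Optional[str] = None
    traits: Optional[str] = None
    qtl_intervals: Optional[str] = None
    simulate: Optional[dict] = None  # SimulationConfig kwargs; replaces inputs
    fdr_max: float = 0.05
    min_abs_log2fc: float = 1.0
    ci_level: float = 0.998
    variance_mode: str = "pooled"
    enrichment_p_max: float = 0.05
    clustering_metric: str = "correlation"
    clustering_linkage: str = "average"
    overlap_rule: str = "contained"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        for name in ("fdr_max", "min_abs_log2fc", "enrichment_p_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc

    # -- inputs (optionally simulated) -------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
            fixdir = outdir / "fixtures"
            write_fixture_set(fixdir, sim_cfg)
            config.counts = str(fixdir / "counts.tsv")
            config.samples = str(fixdir / "samples.tsv")
            config.genes = str(fixdir / "genes.tsv")
            config.terms = config.terms or str(fixdir / "terms.tsv")
            config.traits = config.traits or str(fixdir / "traits.tsv")
            config.qtl_intervals = config.qtl_intervals or str(
                fixdir / "qtl_intervals.tsv"
            )
            record("simulate", n_genes=sim_cfg.n_genes, seed=sim_cfg.seed)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("simulate", exc)

    try:
        for key in ("counts", "samples", "genes"):
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"required input {key!r} not found: {path}")
        for key in ("counts", "samples", "genes", "terms", "traits", "qtl_intervals"):
            path = getattr(config, key)
            if path and Path(path).exists():
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(Path(path))}
        matrix = read_expression_set(config.counts, config.samples, config.genes)
        rpkm = compute_rpkm(matrix)
        logx = np.log2(rpkm.values + 1.0)
        rpkm.values.to_csv(outdir / "rpkm.tsv", sep="\t", index_label="gene_id")
        logx.to_csv(outdir / "log2_rpkm.tsv", sep="\t", index_label="gene_id")
        det = detection_summary(matrix)
        record(
            "normalize",
            n_genes=matrix.n_genes,
            n_samples=len(matrix.sample_ids),
            detected=det[0],
            detected_fraction=round(det[2], 6),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("normalize", exc)

    # -- DE testing and partitioning per stage -----------------------------
    dg_hp_by_stage: dict[str, frozenset] = {}
    try:
        for stage in matrix.stages:
            contrasts = trio_contrasts(matrix, stage)
            deg_sets = {}
            for label, contrast in contrasts.items():
                disp = estimate_dispersion(matrix, contrast)
                res = de_test(
                    matrix,
                    contrast,
                    dispersion=disp,
                    fdr_max=config.fdr_max,
                    min_abs_log2fc=config.min_abs_log2fc,
                )
                tag = label.replace("/", "")
                res.to_csv(outdir / f"de_{stage}_{tag}.tsv", sep="\t", index_label="gene_id")
                deg_sets[label] = set(res.index[res["is_deg"]])
            part = partition_degs(deg_sets, stage)
            dg_hp_by_stage[stage] = part.dg_hp
            venn = pd.DataFrame(
                [{"region": k, "count": v} for k, v in part.venn.items()]
            )
            venn.to_csv(outdir / f"venn_{stage}.tsv", sep="\t", index=False)
            record(
                f"de_{stage}",
                **{k.replace("/", ""): v for k, v in part.per_contrast.items()},
                dg_hp=len(part.dg_hp),
                dg_pp=len(part.dg_pp),
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("de", exc)

    # -- trio ANOVA + h_p classification -----------------------------------
    try:
        for stage in matrix.stages:
            effects = fit_trio_anova(logx, matrix.samples, stage)
            effects = classify_hp(
                effects, level=config.ci_level, variance_mode=config.variance_mode
            )
            effects.table.to_csv(
                outdir / f"trio_effects_{stage}.tsv", sep="\t", index_label="gene_id"
            )
            summary = summarize_patterns(effects, dg_hp_by_stage.get(stage, ()))
            summary.to_csv(outdir / f"pattern_summary_{stage}.tsv", sep="\t")
            record(f"classify_{stage}", n_classified=len(effects.table))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("classify", exc)

    # -- phenotype heterosis ----------------------------------------------
    if config.traits and Path(config.traits).exists():
        try:
            traits = read_traits(config.traits)
            het = heterosis_table(traits)
            het.to_csv(outdir / "heterosis.tsv", sep="\t")
            record("heterosis", n_traits=len(het))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("heterosis", exc)

    # -- enrichment of DG_HP against the detected background --------------
    if config.terms and Path(config.terms).exists():
        try:
            annotation = read_terms(config.terms)
            detected = set(matrix.gene_ids[matrix.counts.sum(axis=1) >= 1])
            for stage, dg_hp in dg_hp_by_stage.items():
                res = enrich(
                    dg_hp & detected,
                    detected,
                    annotation,
                    p_max=config.enrichment_p_max,
                )
                res.to_csv(outdir / f"enrichment_{stage}.tsv", sep="\t", index=False)
                record(f"enrich_{stage}", n_terms=len(res))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("enrich", exc)

    # -- sample clustering --------------------------------------------------
    try:
        tree = cluster_samples(
            logx, metric=config.clustering_metric, linkage=config.clustering_linkage
        )
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        pd.DataFrame({"sample_id": tree.leaf_order}).to_csv(
            outdir / "leaf_order.tsv", sep="\t", index=False
        )
        record("cluster", n_samples=tree.n_leaves)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("cluster", exc)

    # -- QTL interval overlap ----------------------------------------------
    if config.qtl_intervals and Path(config.qtl_intervals).exists():
        try:
            if matrix.gene_coords is None:
                raise ValueError("gene annotation lacks coordinates for QTL overlap")
            intervals = read_qtl_intervals(config.qtl_intervals)
            all_hp = frozenset().union(*dg_hp_by_stage.values()) if dg_hp_by_stage else frozenset()
            overlaps = map_genes_to_intervals(
                matrix.gene_coords,
                intervals,
                rule=config.overlap_rule,
                gene_subset=all_hp if all_hp else None,
            )
            overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
            record("qtl_overlap", n_hits=len(overlaps))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("qtl_overlap", exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
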