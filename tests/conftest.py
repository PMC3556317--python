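import numpy as np
import pandas as pd
import pytest

from triohet.expression import ExpressionMatrix
from triohet.simulate import SimulationConfig, simulate_trio_counts


def make_matrix(counts, lengths=None, stage="tillering", coords=None):
    """Build a one-stage trio ExpressionMatrix from a genes x 6 array.

    Column order: P1_r1, P1_r2, P2_r1, P2_r2, F1_r1, F1_r2.
    """
    counts = np.asarray(counts)
    n_genes = counts.shape[0]
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cols = []
    meta = []
    for geno in ("P1", "P2", "F1"):
        for rep in (1, 2):
            sid = f"{geno}_{stage}_r{rep}"
            cols.append(sid)
            meta.append({"sample_id": sid, "genotype": geno, "stage": stage, "replicate": rep})
    if lengths is None:
        lengths = np.full(n_genes, 1000)
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=cols),
        samples=pd.DataFrame(meta).set_index("sample_id"),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        gene_coords=coords,
    )


@pytest.fixture(scope="session")
def sim_small():
    """300-gene trio simulation shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=300, seed=11)
    return simulate_trio_counts(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from triohet.simulate import write_fixture_set

    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixture_set(outdir, SimulationConfig(n_genes=200, seed=5))
    return outdir, manifest
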