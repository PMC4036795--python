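import numpy as np
import pytest

import renscan as rs


@pytest.fixture
def params():
    return rs.PipelineParams()


@pytest.fixture(scope="session")
def small_truth():
    """A compact truth set shared by read-level tests: 8 genes, one gap."""
    p = rs.PipelineParams()
    return rs.simulate_truth(
        p,
        n_genes_per_class={"CC-NB-LRR": 3, "TIR-NB-LRR": 2, "NB": 2, "LRR": 1},
        n_gaps=1, gap_len_range=(150, 400),
        cluster_spec=(), seed=11, genome_len=150_000,
    )


@pytest.fixture(scope="session")
def default_truth():
    """The default study conditions: ~1 Mb genome, 30 genes over all eight
    domain classes, one planted cluster, three gaps."""
    p = rs.PipelineParams()
    return rs.simulate_truth(p, seed=1)


def random_models(rng, n, seq_ids=("chr1", "chr2"), span=100_000, prefix="g"):
    """Random non-degenerate gene models for reconciliation/cluster tests."""
    models = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(200, 3000))
        models.append(rs.GeneModel(
            gene_id=f"{prefix}{i:04d}",
            seq_id=str(seq_ids[int(rng.integers(len(seq_ids)))]),
            strand="+-"[int(rng.integers(2))],
            start=start, end=start + length,
            gene_class="NB", completeness="partial",
        ))
    return models
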