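import numpy as np
import pandas as pd
import pytest

from piezoreg.expression_norm import CountMatrix
from piezoreg.sequence_io import GeneModel, GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytes(bases[rng.integers(0, 4, size=1000)]).decode()
    return GenomeRecord("c1", seq)


@pytest.fixture
def plus_gene():
    return GeneModel("G_PLUS", "c1", 301, 600, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("G_MINUS", "c1", 101, 400, "-")


def make_count_matrix(counts, conditions, lengths=None):
    """Tiny CountMatrix builder: counts is a 2D array, conditions one label
    per column; replicate labels are assigned within condition."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    reps = {}
    sample_ids = []
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        sample_ids.append(f"{c}_r{reps[c]}")
    design = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": [sid.split("_r")[-1] for sid in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if lengths is None:
        lengths = [1000] * n_genes
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=genes),
        design=design,
    )


@pytest.fixture
def count_matrix_3x3(rng):
    counts = rng.poisson(200, size=(50, 9))
    return make_count_matrix(
        counts, ["0.1MPa"] * 3 + ["50MPa"] * 3 + ["90MPa"] * 3
    )
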