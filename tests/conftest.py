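import numpy as np
import pytest

from linamp.ampsim import MoleculePool, ReadSet


def make_readset(triples, n_cells, n_genes, umi_length=4, read_budget=0):
    """Build a ReadSet directly from integer (cell, gene, umi) triples."""
    triples = list(triples)
    cell = np.array([t[0] for t in triples], dtype=np.int64)
    gene = np.array([t[1] for t in triples], dtype=np.int64)
    umi = np.array([t[2] for t in triples], dtype=np.int64)
    return ReadSet(
        cell=cell,
        gene=gene,
        umi=umi,
        cell_ids=np.array([f"BC{i:03d}" for i in range(n_cells)]),
        gene_ids=np.array([f"G{j:03d}" for j in range(n_genes)]),
        umi_length=umi_length,
        read_budget=read_budget or (len(triples) or 1),
    )


def make_pool(cell, gene, umi, copies=None, eligible=None, n_cells=None, n_genes=None,
              umi_length=4):
    """Build a MoleculePool from parallel integer arrays."""
    cell = np.asarray(cell, dtype=np.int64)
    gene = np.asarray(gene, dtype=np.int64)
    umi = np.asarray(umi, dtype=np.int64)
    n = len(cell)
    n_cells = n_cells or (int(cell.max()) + 1 if n else 1)
    n_genes = n_genes or (int(gene.max()) + 1 if n else 1)
    return MoleculePool(
        cell=cell,
        gene=gene,
        umi=umi,
        copies=np.ones(n, dtype=np.int64) if copies is None else np.asarray(copies, dtype=np.int64),
        eligible=np.ones(n, dtype=bool) if eligible is None else np.asarray(eligible, dtype=bool),
        cell_ids=np.array([f"BC{i:03d}" for i in range(n_cells)]),
        gene_ids=np.array([f"G{j:03d}" for j in range(n_genes)]),
        umi_length=umi_length,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
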