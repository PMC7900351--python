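"""Deduplication and benchmark statistics against brute-force oracles."""

from collections import Counter, defaultdict

import numpy as np
import pandas as pd
import pytest

from linamp.errors import ValidationError
from linamp.libmetrics import (
    cell_qc_filter,
    deduplicate,
    detected_genes,
    downsample_reads,
    dropout_profile,
    duplication_rate,
    on_target_fraction,
    sensitivity_fold,
)
from linamp.paneldesign import random_panel

from conftest import make_readset


def dedup_oracle(reads):
    """Independent tally: distinct (cell, gene, umi) triples via python sets."""
    per_pair = defaultdict(set)
    for c, g, u in zip(reads.cell, reads.gene, reads.umi):
        per_pair[(int(c), int(g))].add(int(u))
    out = np.zeros((len(reads.cell_ids), len(reads.gene_ids)), dtype=int)
    for (c, g), umis in per_pair.items():
        out[c, g] = len(umis)
    return out


def random_readset(rng, n_reads, n_cells=10, n_genes=20, n_umis=50):
    return make_readset(
        zip(
            rng.integers(0, n_cells, n_reads),
            rng.integers(0, n_genes, n_reads),
            rng.integers(0, n_umis, n_reads),
        ),
        n_cells, n_genes,
    )


def test_deduplicate_counts_distinct_triples():
    rs = make_readset([(0, 0, 1), (0, 0, 1), (0, 0, 2), (0, 1, 3)], 2, 2)
    counts = deduplicate(rs)
    assert counts.X.toarray().tolist() == [[2, 1], [0, 0]]
    assert counts.obs["total_reads"].tolist() == [4, 0]
    assert counts.obs["total_umis"].tolist() == [3, 0]


def test_deduplicate_empty_readset():
    rs = make_readset([], 3, 4)
    counts = deduplicate(rs)
    assert counts.shape == (3, 4)
    assert counts.X.nnz == 0


@pytest.mark.parametrize("seed", range(5))
def test_deduplicate_matches_set_cardinality_oracle(seed):
    rng = np.random.default_rng(seed)
    rs = random_readset(rng, 1_000)
    assert np.array_equal(deduplicate(rs).X.toarray(), dedup_oracle(rs))


def test_duplication_rate_bounds_and_oracle(rng):
    rs = make_readset([(0, 0, 1)] * 10, 1, 1)
    counts = deduplicate(rs)
    assert duplication_rate(rs, counts).iloc[0] == 10.0
    rs = make_readset([(0, 0, u) for u in range(10)], 1, 1)
    assert duplication_rate(rs, deduplicate(rs)).iloc[0] == 1.0
    rs = random_readset(rng, 2_000)
    counts = deduplicate(rs)
    rate = duplication_rate(rs, counts)
    per_cell_reads = Counter(rs.cell.tolist())
    triples = {(int(c), int(g), int(u)) for c, g, u in zip(rs.cell, rs.gene, rs.umi)}
    for c in range(len(rs.cell_ids)):
        umis = sum(1 for t in triples if t[0] == c)
        assert rate.iloc[c] == pytest.approx(per_cell_reads[c] / umis)
    # reads = duplication_rate x UMIs, exactly, per cell
    prod = rate.to_numpy() * counts.obs["total_umis"].to_numpy()
    assert np.allclose(prod, counts.obs["total_reads"].to_numpy())


def test_duplication_rate_flags_zero_umi_cells():
    rs = make_readset([(0, 0, 1)], 2, 1)
    rate = duplication_rate(rs, deduplicate(rs))
    assert np.isnan(rate.iloc[1])


def test_dropout_profile_and_detection_boundary(rng):
    # gene 0 in 5/10 cells (boundary, detected), gene 1 in 4/10 (not detected)
    triples = [(c, 0, c) for c in range(5)] + [(c, 1, c) for c in range(4)]
    triples += [(c, 2, c) for c in range(10)]
    rs = make_readset(triples, 10, 4)
    counts = deduplicate(rs)
    prof = dropout_profile(counts)
    assert prof.tolist() == [0.5, 0.6, 0.0, 1.0]
    hit, n = detected_genes(counts, 0.5)
    assert set(hit) == {"G000", "G002"} and n == 2
    with pytest.raises(ValidationError):
        detected_genes(counts, 1.0)
    # oracle: thresholding the dropout profile column-wise
    rs = random_readset(rng, 3_000, n_genes=49)
    counts = deduplicate(rs)
    dense = counts.X.toarray()
    manual = [
        g for j, g in enumerate(counts.var_names)
        if (dense[:, j] == 0).mean() <= 0.5
    ]
    assert detected_genes(counts, 0.5)[0] == manual


def test_on_target_fraction_ratio():
    rs = make_readset([(0, 0, u) for u in range(93)] + [(0, 1, u) for u in range(7)], 1, 2)
    panel = random_panel(["G000"], seed=0, max_dimer=None)
    assert on_target_fraction(rs, panel) == pytest.approx(0.93)
    panel_all = random_panel(["G000", "G001"], seed=0, max_dimer=None)
    assert on_target_fraction(rs, panel_all) == 1.0
    with pytest.raises(ValidationError):
        on_target_fraction(make_readset([], 1, 2), panel)


def test_downsample_exact_thinning_and_flags(rng):
    rs = random_readset(rng, 5_000, n_cells=5)
    ds = downsample_reads(rs, 300, seed=1)
    assert (ds.reads_per_cell() == 300).all()
    # depth at or above availability leaves the read multiset unchanged
    same = downsample_reads(rs, 10_000, seed=1)
    assert sorted(zip(same.cell, same.gene, same.umi)) == sorted(
        zip(rs.cell, rs.gene, rs.umi)
    )
    assert set(same.underfilled_cells.tolist()) == set(range(5))


@pytest.mark.parametrize("seed", range(3))
def test_downsample_umi_monotonicity(seed):
    rng = np.random.default_rng(seed)
    rs = random_readset(rng, 4_000, n_cells=8)
    full = deduplicate(rs)
    ds = downsample_reads(rs, 200, seed=seed)
    sub = deduplicate(ds)
    assert (sub.X.toarray() <= full.X.toarray()).all()
    # and the thinned multiset is a true sub-multiset of the original
    before = Counter(zip(rs.cell.tolist(), rs.gene.tolist(), rs.umi.tolist()))
    after = Counter(zip(ds.cell.tolist(), ds.gene.tolist(), ds.umi.tolist()))
    assert all(after[k] <= before[k] for k in after)


def test_downsample_is_deterministic():
    rng = np.random.default_rng(9)
    rs = random_readset(rng, 2_000)
    a = downsample_reads(rs, 100, seed=5)
    b = downsample_reads(rs, 100, seed=5)
    assert np.array_equal(a.umi, b.umi) and np.array_equal(a.cell, b.cell)


def test_sensitivity_fold_identity_scaling_and_oracle(rng):
    rs = random_readset(rng, 2_000)
    counts = deduplicate(rs)
    table, summary = sensitivity_fold(counts, counts)
    expressed = table["in_summary"]
    assert np.allclose(table.loc[expressed, "fold"], 1.0)
    assert summary == pytest.approx(1.0)
    ten = counts.copy()
    ten.X = counts.X * 10
    table, summary = sensitivity_fold(ten, counts)
    assert np.allclose(table.loc[table["in_summary"], "fold"], 10.0)
    assert summary == pytest.approx(10.0)
    other = deduplicate(random_readset(rng, 2_000))
    table, _ = sensitivity_fold(counts, other)
    ma = counts.X.toarray().mean(axis=0)
    mb = other.X.toarray().mean(axis=0)
    for j in range(len(ma)):
        if mb[j] > 0:
            assert table["fold"].iloc[j] == pytest.approx(ma[j] / mb[j])


def test_sensitivity_fold_flags_undefined_genes():
    a = deduplicate(make_readset([(0, 0, 1)], 1, 3))
    b = deduplicate(make_readset([(0, 1, 1)], 1, 3))
    table, summary = sensitivity_fold(a, b)
    assert not table.loc["G002", "defined"]  # absent from both
    assert np.isinf(table.loc["G000", "fold"])  # zero denominator, flagged out
    assert not table.loc["G000", "in_summary"]
    assert table.loc["G001", "fold"] == 0.0  # zero numerator: no geometric mean
    assert not table.loc["G001", "in_summary"]
    assert np.isnan(summary)  # nothing summarisable in this degenerate pair


def test_cell_qc_filter_predicate_and_log(rng):
    rs = random_readset(rng, 1_500)
    counts = deduplicate(rs)
    kept, log = cell_qc_filter(counts, min_umis=0, min_genes=0)
    assert kept.shape == counts.shape and log.empty
    total = np.asarray(counts.X.sum(axis=1)).ravel()
    ngene = np.asarray((counts.X > 0).sum(axis=1)).ravel()
    kept, log = cell_qc_filter(counts, min_umis=120, min_genes=15)
    manual = (total >= 120) & (ngene >= 15)
    assert list(kept.obs_names) == list(counts.obs_names[manual])
    assert len(log) == int((~manual).sum())


def test_cell_qc_filter_removes_shallow_cell():
    counts = deduplicate(make_readset([(0, 0, u) for u in range(5)], 1, 1))
    kept, log = cell_qc_filter(counts, min_umis=10, min_genes=0)
    assert kept.n_obs == 0
    assert len(log) == 1 and "umis 5 < 10" in log["reason"].iloc[0]
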