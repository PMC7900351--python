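"""Amplification simulators: closed-form moments, eligibility rules, sampling."""

import numpy as np
import pytest
from scipy import stats

from linamp.ampsim import (
    AmplificationParams,
    amplify_exponential,
    amplify_linear,
    sample_reads,
)
from linamp.errors import ValidationError
from linamp.paneldesign import random_panel

from conftest import make_pool


def _panel_for(pool, genes=None):
    genes = list(pool.gene_ids) if genes is None else genes
    return random_panel(genes, seed=0, max_dimer=None)


def test_exponential_perfect_efficiency_doubles_each_cycle():
    pool = make_pool([0], [0], [5])
    out = amplify_exponential(pool, AmplificationParams(n_cycles=3, efficiency=1.0), 0)
    assert out.copies.tolist() == [8]  # 2^3
    assert out.eligible.all()


def test_exponential_zero_efficiency_leaves_one_copy():
    pool = make_pool([0, 0], [0, 1], [1, 2])
    out = amplify_exponential(pool, AmplificationParams(n_cycles=10, efficiency=0.0), 0)
    assert (out.copies == 1).all()


def test_exponential_mean_matches_galton_watson():
    n = 10_000
    pool = make_pool(np.zeros(n), np.zeros(n), np.arange(n), umi_length=10)
    out = amplify_exponential(pool, AmplificationParams(n_cycles=10, efficiency=0.8), 1)
    mean = 1.8**10
    # Galton-Watson variance after n cycles with Bernoulli(e) offspring increment
    e, m = 0.8, 1.8
    var = e * (1 - e) * m ** (10 - 1) * (m**10 - 1) / (m - 1)
    assert abs(out.copies.mean() - mean) < 3 * np.sqrt(var / n)
    assert (out.copies >= 1).all()


def test_exponential_requires_every_gene_efficiency():
    pool = make_pool([0, 0], [0, 1], [1, 2])
    eff = {str(pool.gene_ids[0]): 0.9}  # second gene missing
    with pytest.raises(ValidationError):
        amplify_exponential(pool, AmplificationParams(n_cycles=2, efficiency=eff), 0)


def test_linear_certain_priming_gives_cycle_count_copies():
    pool = make_pool([0, 1], [0, 0], [3, 4])
    out = amplify_linear(
        pool, _panel_for(pool), AmplificationParams(n_cycles=10, priming_probability=1.0), 0
    )
    assert (out.copies[out.eligible] == 10).all()
    assert int(out.eligible.sum()) == 2
    # the bead-bound template survives but cannot be sequenced
    assert int((~out.eligible).sum()) == 2
    assert (out.copies[~out.eligible] == 1).all()


def test_linear_no_priming_and_no_offtarget_yields_nothing():
    pool = make_pool([0, 0], [0, 1], [1, 2], n_genes=2)
    panel = _panel_for(pool, [str(pool.gene_ids[0])])  # gene 1 off panel
    out = amplify_linear(
        pool, panel,
        AmplificationParams(n_cycles=12, priming_probability=0.0, offtarget_rate=0.0), 0,
    )
    assert not out.eligible.any()


def test_linear_copies_match_binomial_moments_and_distribution():
    n, p, cyc = 10_000, 0.8, 12
    pool = make_pool(np.zeros(n), np.zeros(n), np.arange(n), umi_length=10)
    out = amplify_linear(
        pool, _panel_for(pool), AmplificationParams(n_cycles=cyc, priming_probability=p), 2
    )
    k = out.copies[out.eligible]
    # records with zero products carry no eligible record at all
    k = np.concatenate([k, np.zeros(n - len(k), dtype=int)])
    mean, var = cyc * p, cyc * p * (1 - p)
    assert abs(k.mean() - mean) < 3 * np.sqrt(var / n)
    assert abs(k.var() - var) / var < 0.1
    # full distributional agreement with Binomial(n_cycles, p)
    support = np.arange(cyc + 1)
    observed = np.bincount(k, minlength=cyc + 1)
    expected = n * stats.binom.pmf(support, cyc, p)
    keep = expected > 5
    chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    assert stats.chi2.sf(chi2, keep.sum() - 1) > 1e-3


def test_linear_warns_for_unexpressed_panel_gene():
    pool = make_pool([0], [0], [1], n_genes=1)
    panel = _panel_for(pool, [str(pool.gene_ids[0]), "GHOST"])
    with pytest.warns(UserWarning, match="absent from the molecule pool"):
        amplify_linear(pool, panel, AmplificationParams(n_cycles=3, priming_probability=0.5), 0)


def test_copy_skew_higher_under_exponential():
    # heterogeneous per-gene efficiency compounds geometrically; linear stays binomial
    n_genes, mols_per_gene = 50, 200
    gene = np.repeat(np.arange(n_genes), mols_per_gene)
    n = len(gene)
    pool = make_pool(np.zeros(n), gene, np.arange(n), n_genes=n_genes, umi_length=10)
    rng = np.random.default_rng(3)
    eff = {f"G{j:03d}": e for j, e in enumerate(rng.uniform(0.7, 0.95, n_genes))}
    exp = amplify_exponential(pool, AmplificationParams(n_cycles=12, efficiency=eff), 4)
    lin = amplify_linear(
        pool, _panel_for(pool), AmplificationParams(n_cycles=12, priming_probability=0.8), 5
    )
    cv = lambda x: x.std() / x.mean()
    assert cv(exp.copies[exp.eligible].astype(float)) > cv(lin.copies[lin.eligible].astype(float))


def test_sample_reads_single_source_and_budget():
    pool = make_pool([0], [0], [7], copies=[5])
    rs = sample_reads(pool, 10, 0)
    assert rs.n_reads == 10
    assert (rs.umi == 7).all() and (rs.gene == 0).all()


def test_sample_reads_proportional_to_copies():
    pool = make_pool([0, 0], [0, 1], [1, 2], copies=[9, 1])
    rs = sample_reads(pool, 10_000, 1)
    share = (rs.gene == 0).mean()
    sd = np.sqrt(0.9 * 0.1 / 10_000)
    assert abs(share - 0.9) < 3 * sd


def test_sample_reads_budget_conservation_across_cells():
    n_cells = 100
    cell = np.repeat(np.arange(n_cells), 5)
    pool = make_pool(cell, np.zeros(len(cell)), np.arange(len(cell)),
                     n_cells=n_cells, umi_length=6)
    rs = sample_reads(pool, 2_000, 2)
    assert rs.n_reads == 2_000 * n_cells
    assert (rs.reads_per_cell() == 2_000).all()


def test_sample_reads_never_invents_triples_and_skips_ineligible():
    rng = np.random.default_rng(4)
    n = 500
    pool = make_pool(rng.integers(0, 10, n), rng.integers(0, 5, n),
                     rng.integers(0, 4**4, n),
                     copies=rng.integers(1, 5, n),
                     eligible=rng.random(n) < 0.6,
                     n_cells=10, n_genes=5)
    rs = sample_reads(pool, 300, 5)
    legal = {
        (c, g, u)
        for c, g, u, e in zip(pool.cell, pool.gene, pool.umi, pool.eligible)
        if e
    }
    seen = set(zip(rs.cell.tolist(), rs.gene.tolist(), rs.umi.tolist()))
    assert seen <= legal


def test_sample_reads_errors_without_eligible_copies():
    pool = make_pool([0], [0], [1], eligible=[False])
    with pytest.raises(ValidationError):
        sample_reads(pool, 10, 0)


def test_sample_reads_flags_cells_without_material():
    pool = make_pool([0, 1], [0, 0], [1, 2], eligible=[True, False], n_cells=2)
    with pytest.warns(UserWarning, match="too few eligible"):
        rs = sample_reads(pool, 50, 0)
    assert rs.underfilled_cells.tolist() == [1]
    assert rs.reads_per_cell().tolist() == [50, 0]


def test_sample_without_replacement_exhausts_copy_population():
    pool = make_pool([0], [0], [9], copies=[5])
    with pytest.warns(UserWarning, match="too few eligible"):
        rs = sample_reads(pool, 10, 0, with_replacement=False)
    assert rs.n_reads == 5  # only five physical copies exist
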