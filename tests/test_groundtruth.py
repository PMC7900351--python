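"""Ground-truth generator: tier apportionment, count distributions, capture."""

import numpy as np
import pytest

from linamp.errors import ValidationError
from linamp.groundtruth import (
    build_expression_model,
    capture_molecules,
    concat_models,
    sample_cells,
)

TIER_MEANS = {"high": 100.0, "medium": 30.0, "low": 8.0}


def test_absent_tier_forces_zero_mean():
    m = build_expression_model(3, {"absent": 1.0}, TIER_MEANS, seed=0)
    assert (m.genes["mean_molecules"] == 0).all()
    assert (m.genes["abundance_tier"] == "absent").all()


def test_negative_control_block_is_exactly_absent():
    # a 52-gene panel carrying 3 absent-tier negative-control targets
    frac = {"high": 0.2 * 49 / 52, "medium": 0.3 * 49 / 52, "low": 0.5 * 49 / 52,
            "absent": 3 / 52}
    m = build_expression_model(52, frac, TIER_MEANS, seed=1)
    assert (m.genes["mean_molecules"] == 0).sum() == 3
    assert (m.genes["abundance_tier"] == "absent").sum() == 3


def test_tier_counts_are_deterministic_proportions():
    # largest-remainder apportionment makes tier sizes exact, not multinomial
    m = build_expression_model(
        1000, {"high": 0.1, "medium": 0.3, "low": 0.6}, TIER_MEANS, seed=7
    )
    counts = m.genes["abundance_tier"].value_counts()
    assert counts["high"] == 100 and counts["medium"] == 300 and counts["low"] == 600


@pytest.mark.parametrize(
    "fractions,means",
    [
        ({"high": 0.6, "low": 0.6}, TIER_MEANS),  # not a simplex
        ({"high": 1.0}, {"high": -5.0}),  # nonpositive mean
        ({"high": 0.5, "low": 0.5}, {"high": 5.0, "low": 10.0}),  # not decreasing
    ],
)
def test_model_validation_errors(fractions, means):
    with pytest.raises(ValidationError):
        build_expression_model(10, fractions, means, seed=0)


def test_zero_mean_gene_is_zero_in_every_cell():
    m = build_expression_model(
        4, {"medium": 0.5, "absent": 0.5}, TIER_MEANS, seed=2
    )
    cells = sample_cells(m, 200, seed=3)
    absent = m.genes["abundance_tier"].to_numpy() == "absent"
    assert (cells.counts[:, absent] == 0).all()
    assert (cells.counts[:, ~absent] > 0).any()


def test_poisson_switch_matches_closed_form_mean():
    # dispersion -> infinity is implemented as a Poisson switch: CLT check
    m = build_expression_model(1, {"medium": 1.0}, {"medium": 5.0},
                               dispersion=np.inf, seed=0, lognormal_sigma=0.0)
    cells = sample_cells(m, 10_000, seed=4)
    x = cells.counts[:, 0]
    se = np.sqrt(5.0 / len(x))
    assert abs(x.mean() - 5.0) < 3 * se
    # Poisson variance equals the mean
    assert abs(x.var() - 5.0) < 0.3


def test_negative_binomial_moments_match_closed_form():
    mu, theta = 20.0, 2.0
    m = build_expression_model(1, {"medium": 1.0}, {"medium": mu},
                               dispersion=theta, seed=0, lognormal_sigma=0.0)
    cells = sample_cells(m, 10_000, seed=5)
    x = cells.counts[:, 0].astype(float)
    var = mu + mu**2 / theta
    assert abs(x.mean() - mu) < 3 * np.sqrt(var / len(x))
    # variance of the sample variance via fourth-moment normal approximation is
    # loose for NB; a 10% band at n = 10,000 is comfortably > 3 SE
    assert abs(x.var() - var) / var < 0.1


def test_condition_multiplier_scales_the_mean():
    m = build_expression_model(1, {"medium": 1.0}, {"medium": 10.0},
                               seed=0, lognormal_sigma=0.0)
    m = m.with_condition_effect("stim", {m.genes.index[0]: 2.0})
    cells = sample_cells(m, 5_000, conditions=["control", "stim"], seed=6)
    ctrl = cells.counts[cells.conditions == "control", 0].astype(float)
    stim = cells.counts[cells.conditions == "stim", 0].astype(float)
    ratio = stim.mean() / ctrl.mean()
    se = ratio * np.sqrt(stim.var() / stim.mean() ** 2 / len(stim)
                         + ctrl.var() / ctrl.mean() ** 2 / len(ctrl))
    assert abs(ratio - 2.0) < 3 * se


def test_unknown_condition_rejected():
    m = build_expression_model(2, {"medium": 1.0}, TIER_MEANS, seed=0)
    with pytest.raises(ValidationError):
        sample_cells(m, 5, conditions=["control", "mystery"], seed=0)


def test_sampling_is_deterministic_given_seed():
    m = build_expression_model(10, {"high": 0.5, "low": 0.5}, TIER_MEANS, seed=0)
    a = sample_cells(m, 50, seed=11)
    b = sample_cells(m, 50, seed=11)
    assert np.array_equal(a.counts, b.counts)
    pa = capture_molecules(a, 0.3, seed=13)
    pb = capture_molecules(b, 0.3, seed=13)
    for f in ("cell", "gene", "umi", "copies"):
        assert np.array_equal(getattr(pa, f), getattr(pb, f))


def test_capture_certain_and_impossible():
    m = build_expression_model(5, {"medium": 1.0}, TIER_MEANS, seed=0)
    cells = sample_cells(m, 20, seed=1)
    full = capture_molecules(cells, 1.0, seed=2)
    assert full.n_records == cells.counts.sum()
    assert (full.copies == 1).all() and not full.eligible.any()
    empty = capture_molecules(cells, 0.0, seed=2)
    assert empty.n_records == 0


def test_capture_rate_matches_binomial_closed_form():
    m = build_expression_model(10, {"medium": 1.0}, {"medium": 50.0}, seed=0)
    cells = sample_cells(m, 200, seed=1)
    n = int(cells.counts.sum())
    assert n > 80_000  # enough molecules for a tight binomial check
    pool = capture_molecules(cells, 0.1, seed=3)
    sd = np.sqrt(n * 0.1 * 0.9)
    assert abs(pool.n_records - 0.1 * n) < 3 * sd


def test_capture_conserves_per_cell_gene_molecules():
    m = build_expression_model(8, {"medium": 0.5, "low": 0.5}, TIER_MEANS, seed=0)
    cells = sample_cells(m, 30, seed=1)
    pool = capture_molecules(cells, 0.6, seed=2)
    got = np.zeros_like(cells.counts)
    np.add.at(got, (pool.cell, pool.gene), 1)
    assert (got <= cells.counts).all()
    assert (pool.umi >= 0).all() and (pool.umi < 4**pool.umi_length).all()


def test_concat_models_merges_conditions_and_rejects_duplicates():
    a = build_expression_model(3, {"medium": 1.0}, TIER_MEANS, seed=0,
                               gene_ids=["A1", "A2", "A3"])
    a = a.with_condition_effect("stim", {"A1": 4.0})
    b = build_expression_model(2, {"low": 1.0}, TIER_MEANS, seed=1,
                               gene_ids=["B1", "B2"])
    m = concat_models(a, b)
    assert m.conditions == ["control", "stim"]
    assert m.multipliers.loc["B1", "stim"] == 1.0
    assert m.multipliers.loc["A1", "stim"] == 4.0
    with pytest.raises(ValidationError):
        concat_models(a, a)
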