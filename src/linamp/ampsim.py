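"""Amplification-regime simulators and fixed-budget read sampling.

Two library-preparation chemistries are contrasted on the same pool of
captured, barcoded cDNA molecules:

* **Exponential (two-primer PCR).**  Every copy is itself a template, so a
  molecule's copy number evolves as a Galton-Watson branching process,
  ``c_{t+1} = c_t + Binomial(c_t, e_g)`` per cycle with a per-gene
  efficiency ``e_g``.  Small efficiency differences compound geometrically,
  which is the mechanism behind amplification bias: after ``n`` cycles the
  expected copy number is ``(1 + e_g)^n``.

* **Linear (single hybrid primer).**  Only the original bead-bound template
  is primed, once per cycle with probability ``p``, and products are never
  re-copied; the number of handle-bearing (sequenceable) copies is exactly
  ``Binomial(n_cycles, p)`` — arithmetic growth with binomial, not
  geometric, dispersion.  Non-panel molecules leak in with a small
  per-cycle off-target priming probability.

Sequencing then draws a fixed read budget per cell, each read landing on a
sequencing-eligible copy with probability proportional to its copy number.
Duplicate reads of the same molecule share its UMI, which is what the
deduplication statistics downstream exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._util import weighted_sample
from .errors import ValidationError
from .paneldesign import GenePanel

__all__ = [
    "MoleculePool",
    "AmplificationParams",
    "ReadSet",
    "amplify_exponential",
    "amplify_linear",
    "sample_reads",
]


@dataclass
class MoleculePool:
    """Captured, barcoded cDNA molecules with post-amplification copy numbers.

    Each record is one original molecule (or, after linear amplification, the
    bundle of handle-bearing copies of one molecule); ``copies`` counts
    identical copies sharing the record's UMI, and only ``eligible`` records
    (those bearing the library adapter) can be sequenced.  ``cell`` and
    ``gene`` are integer indices into ``cell_ids`` / ``gene_ids``; ``umi`` is
    an integer code in ``[0, 4**umi_length)``.
    """

    cell: np.ndarray
    gene: np.ndarray
    umi: np.ndarray
    copies: np.ndarray
    eligible: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    umi_length: int

    def __post_init__(self):
        n = len(self.cell)
        for name in ("gene", "umi", "copies", "eligible"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"MoleculePool field {name} has mismatched length")
        if n and (self.copies < 0).any():
            raise ValidationError("copies must be nonnegative")

    @property
    def n_records(self) -> int:
        return len(self.cell)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total_eligible_copies(self) -> int:
        return int(self.copies[self.eligible].sum())

    def eligible_copies_per_cell(self) -> np.ndarray:
        w = np.where(self.eligible, self.copies, 0)
        return np.bincount(self.cell, weights=w, minlength=self.n_cells).astype(np.int64)


@dataclass(frozen=True)
class AmplificationParams:
    """Knobs of either regime; probabilities are all in [0, 1].

    ``efficiency`` (exponential) may be a scalar or a per-gene mapping;
    ``priming_probability`` and ``offtarget_rate`` drive the linear regime.
    """

    n_cycles: int
    efficiency: float | Mapping[str, float] | None = None
    priming_probability: float | None = None
    offtarget_rate: float = 0.0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be a positive integer")
        for name in ("priming_probability", "offtarget_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if isinstance(self.efficiency, (int, float)) and not 0.0 <= self.efficiency <= 1.0:
            raise ValidationError(f"efficiency={self.efficiency} outside [0, 1]")


@dataclass
class ReadSet:
    """Sequenced reads: a multiset of (cell barcode, UMI, gene) triples.

    Reads keep the pool's integer encoding plus the id tables needed to
    decode them; ``underfilled_cells`` lists cells that could not fill the
    per-cell budget (no or too few eligible molecules).
    """

    cell: np.ndarray
    gene: np.ndarray
    umi: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    umi_length: int
    read_budget: int
    underfilled_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n_reads(self) -> int:
        return len(self.cell)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def reads_per_cell(self) -> np.ndarray:
        return np.bincount(self.cell, minlength=self.n_cells).astype(np.int64)


def _resolve_efficiency(pool: MoleculePool, efficiency) -> np.ndarray:
    """Per-gene efficiency vector aligned to pool.gene_ids."""
    if efficiency is None:
        raise ValidationError("exponential regime requires an efficiency")
    if isinstance(efficiency, (int, float)):
        return np.full(len(pool.gene_ids), float(efficiency))
    eff = np.empty(len(pool.gene_ids))
    missing = []
    for i, g in enumerate(pool.gene_ids):
        if g in efficiency:
            eff[i] = efficiency[g]
        else:
            missing.append(g)
    if missing:
        raise ValidationError(f"missing per-gene efficiency for: {missing[:5]}")
    if ((eff < 0) | (eff > 1)).any():
        raise ValidationError("per-gene efficiencies must lie in [0, 1]")
    return eff


def amplify_exponential(
    pool: MoleculePool, params: AmplificationParams, seed: int
) -> MoleculePool:
    """Two-primer PCR: every record's copies follow a Galton-Watson process.

    After ``n_cycles`` with per-gene efficiency ``e_g``, a record started at
    one copy has mean ``(1 + e_g)**n_cycles`` copies and never fewer than it
    began with.  All resulting copies carry both adapters, so every record
    becomes sequencing-eligible.
    """
    if pool.n_records and (pool.copies < 1).any():
        raise ValidationError("exponential amplification requires copies >= 1 per record")
    eff = _resolve_efficiency(pool, params.efficiency)
    rng = np.random.default_rng(seed)
    copies = pool.copies.astype(np.int64).copy()
    e_rec = eff[pool.gene]
    for _ in range(params.n_cycles):
        copies += rng.binomial(copies, e_rec)
    return replace(
        pool,
        copies=copies,
        eligible=np.ones(pool.n_records, dtype=bool),
        umi=pool.umi.copy(),
        cell=pool.cell.copy(),
        gene=pool.gene.copy(),
    )


def amplify_linear(
    pool: MoleculePool, panel: GenePanel, params: AmplificationParams, seed: int
) -> MoleculePool:
    """Single-primer linear amplification of a panel over the captured pool.

    Each cycle primes only the original template, never a product, so a panel
    molecule ends with ``Binomial(n_cycles, p)`` handle-bearing copies; the
    template itself stays in the pool but is not sequencing-eligible (it lacks
    the library adapter).  Non-panel molecules are primed with the small
    per-cycle ``offtarget_rate``.  Copies inherit the template's barcode and
    UMI.
    """
    if not len(panel):
        raise ValidationError("panel is empty")
    if params.priming_probability is None:
        raise ValidationError("linear regime requires priming_probability")
    pool_genes = set(map(str, pool.gene_ids))
    absent = [g for g in panel.gene_ids if g not in pool_genes]
    if absent:
        warnings.warn(
            f"{len(absent)} panel genes absent from the molecule pool "
            f"(unexpressed targets): {absent[:5]}",
            stacklevel=2,
        )
    on_panel_gene = np.isin(pool.gene_ids, list(panel.gene_ids))
    rng = np.random.default_rng(seed)
    p_rec = np.where(
        on_panel_gene[pool.gene], params.priming_probability, params.offtarget_rate
    )
    k = rng.binomial(params.n_cycles, p_rec).astype(np.int64)
    made = k > 0
    # originals stay (ineligible templates), products appended with eligible=True
    cell = np.concatenate([pool.cell, pool.cell[made]])
    gene = np.concatenate([pool.gene, pool.gene[made]])
    umi = np.concatenate([pool.umi, pool.umi[made]])
    copies = np.concatenate([pool.copies, k[made]])
    eligible = np.concatenate(
        [np.zeros(pool.n_records, dtype=bool), np.ones(int(made.sum()), dtype=bool)]
    )
    return replace(pool, cell=cell, gene=gene, umi=umi, copies=copies, eligible=eligible)


def sample_reads(
    pool: MoleculePool,
    read_budget_per_cell: int,
    seed: int,
    *,
    with_replacement: bool = True,
) -> ReadSet:
    """Sequence a fixed per-cell read budget from the eligible copies.

    Each read independently selects a sequencing-eligible record with
    probability proportional to its copy number (with replacement; copy
    numbers dwarf read depth after amplification).  A cell with at least one
    eligible copy yields exactly the budget; a cell with none yields zero
    reads and is flagged.  ``with_replacement=False`` draws reads from the
    finite copy population instead, for degenerate small pools.
    """
    if read_budget_per_cell < 1:
        raise ValidationError("read_budget_per_cell must be >= 1")
    weights = np.where(pool.eligible, pool.copies, 0).astype(np.float64)
    if weights.sum() == 0:
        raise ValidationError("pool has no sequencing-eligible copies")
    order = np.argsort(pool.cell, kind="stable")
    cell_sorted = pool.cell[order]
    bounds = np.searchsorted(cell_sorted, np.arange(pool.n_cells + 1))
    rng = np.random.default_rng(seed)
    picked: list[np.ndarray] = []
    underfilled = []
    for c in range(pool.n_cells):
        seg = order[bounds[c] : bounds[c + 1]]
        w = weights[seg]
        total = w.sum()
        if total == 0:
            underfilled.append(c)
            continue
        if with_replacement:
            idx = seg[weighted_sample(rng, w, read_budget_per_cell)]
        else:
            expanded = np.repeat(seg, pool.copies[seg] * pool.eligible[seg])
            take = min(read_budget_per_cell, len(expanded))
            if take < read_budget_per_cell:
                underfilled.append(c)
            idx = rng.choice(expanded, size=take, replace=False)
        picked.append(idx)
    if underfilled:
        warnings.warn(
            f"{len(underfilled)} cells had too few eligible copies to fill the "
            f"read budget of {read_budget_per_cell}",
            stacklevel=2,
        )
    sel = np.concatenate(picked) if picked else np.array([], dtype=np.int64)
    return ReadSet(
        cell=pool.cell[sel],
        gene=pool.gene[sel],
        umi=pool.umi[sel],
        cell_ids=pool.cell_ids,
        gene_ids=pool.gene_ids,
        umi_length=pool.umi_length,
        read_budget=read_budget_per_cell,
        underfilled_cells=np.array(underfilled, dtype=np.int64),
    )
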