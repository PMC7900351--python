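"""Synthetic ground truth: expression models, cell sampling, molecule capture.

Emulates the statistical structure of a PBMC-style droplet experiment:
genes fall into high/medium/low abundance tiers (plus an ``absent`` tier
for negative-control targets), per-cell molecule counts are
negative-binomially dispersed around per-gene means, a second condition
acts multiplicatively on those means, and bead capture keeps each molecule
independently with a fixed probability, attaching the cell barcode and a
uniform random UMI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ampsim import MoleculePool
from .errors import ValidationError

__all__ = [
    "TIERS",
    "ExpressionModel",
    "GroundTruthCells",
    "build_expression_model",
    "concat_models",
    "sample_cells",
    "capture_molecules",
    "index_to_barcode",
]

TIERS = ("high", "medium", "low", "absent")


@dataclass
class ExpressionModel:
    """Per-gene expression parameters and per-condition fold effects.

    ``genes`` is indexed by gene_id with columns ``abundance_tier``,
    ``mean_molecules`` (expected true molecules per cell in the reference
    condition) and ``dispersion`` (negative-binomial size; ``inf`` means
    Poisson).  ``multipliers`` is genes x conditions; the reference condition
    is all ones, and a stimulation is a column of per-gene fold effects.
    """

    genes: pd.DataFrame
    multipliers: pd.DataFrame
    reference_condition: str = "control"

    def __post_init__(self):
        if not self.genes.index.equals(self.multipliers.index):
            raise ValidationError("genes and multipliers must share the same gene index")
        if self.reference_condition not in self.multipliers.columns:
            raise ValidationError(
                f"reference condition {self.reference_condition!r} missing from multipliers"
            )
        if not np.allclose(self.multipliers[self.reference_condition], 1.0):
            raise ValidationError("reference-condition multipliers must all equal 1")
        tier = self.genes["abundance_tier"]
        mean = self.genes["mean_molecules"]
        if (mean < 0).any() or not np.isfinite(mean).all():
            raise ValidationError("mean_molecules must be finite and nonnegative")
        absent_bad = (tier == "absent") != (mean == 0)
        if absent_bad.any():
            raise ValidationError(
                "mean_molecules must be zero exactly for absent-tier genes; offending "
                f"genes: {list(self.genes.index[absent_bad][:5])}"
            )
        if (self.multipliers.to_numpy() <= 0).any():
            raise ValidationError("condition multipliers must be positive")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes.index.to_numpy()

    @property
    def conditions(self) -> list[str]:
        return list(self.multipliers.columns)

    def with_condition_effect(
        self, condition: str, effects: Mapping[str, float] | None = None
    ) -> "ExpressionModel":
        """Declare a condition whose mean is ``effects[gene]``-fold the reference.

        Genes not named in ``effects`` keep multiplier 1.
        """
        mult = self.multipliers.copy()
        mult[condition] = 1.0
        if effects:
            unknown = set(effects) - set(self.genes.index)
            if unknown:
                raise ValidationError(f"effects name unknown genes: {sorted(unknown)[:5]}")
            for g, f in effects.items():
                if f <= 0:
                    raise ValidationError(f"multiplier for {g} must be positive, got {f}")
                mult.loc[g, condition] = float(f)
        return ExpressionModel(self.genes, mult, self.reference_condition)


def _largest_remainder(fractions: np.ndarray, n: int) -> np.ndarray:
    """Apportion n items to categories so counts match fractions up to rounding."""
    quota = fractions * n
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    if rem:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def build_expression_model(
    n_genes: int,
    tier_fractions: Mapping[str, float],
    tier_means: Mapping[str, float],
    dispersion: float = 2.0,
    seed: int = 0,
    *,
    gene_ids: Sequence[str] | None = None,
    lognormal_sigma: float = 0.5,
    reference_condition: str = "control",
) -> ExpressionModel:
    """Assign genes to abundance tiers and draw per-gene means around tier means.

    Tier membership is deterministic-proportional (largest remainder in the
    fixed tier order high, medium, low, absent), so tier counts are exact.
    Within a tier, per-gene means are log-normal around the tier mean with a
    mean-preserving correction; the ``absent`` tier is identically zero and
    models negative-control targets.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    unknown = set(tier_fractions) - set(TIERS)
    if unknown:
        raise ValidationError(f"unknown tiers: {sorted(unknown)}")
    frac = np.array([float(tier_fractions.get(t, 0.0)) for t in TIERS])
    if (frac < 0).any() or abs(frac.sum() - 1.0) > 1e-9:
        raise ValidationError("tier_fractions must be nonnegative and sum to 1")
    means = {t: float(tier_means.get(t, 0.0)) for t in TIERS}
    for t in TIERS[:3]:
        if frac[TIERS.index(t)] > 0 and means[t] <= 0:
            raise ValidationError(f"tier mean for {t!r} must be positive")
    present = [t for t in TIERS[:3] if frac[TIERS.index(t)] > 0]
    vals = [means[t] for t in present]
    if any(a <= b for a, b in zip(vals, vals[1:])):
        raise ValidationError("tier means must be strictly decreasing high > medium > low")
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive (np.inf selects Poisson)")

    counts = _largest_remainder(frac, n_genes)
    tiers = np.repeat(TIERS, counts)
    if gene_ids is None:
        width = max(4, len(str(n_genes)))
        gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_genes)
    tier_mu = np.array([means[t] for t in tiers])
    jitter = np.exp(lognormal_sigma * z - lognormal_sigma**2 / 2.0)
    mean_molecules = np.where(tiers == "absent", 0.0, tier_mu * jitter)

    genes = pd.DataFrame(
        {
            "abundance_tier": tiers,
            "mean_molecules": mean_molecules,
            "dispersion": float(dispersion),
        },
        index=pd.Index(list(gene_ids), name="gene_id"),
    )
    mult = pd.DataFrame({reference_condition: 1.0}, index=genes.index)
    return ExpressionModel(genes, mult, reference_condition)


def concat_models(*models: ExpressionModel) -> ExpressionModel:
    """Stack disjoint gene blocks (e.g., a targeted panel plus background
    transcriptome) into one model; conditions are unioned with multiplier 1
    where a block did not declare them."""
    ref = models[0].reference_condition
    if any(m.reference_condition != ref for m in models):
        raise ValidationError("all blocks must share the reference condition")
    genes = pd.concat([m.genes for m in models])
    if genes.index.has_duplicates:
        dup = genes.index[genes.index.duplicated()][0]
        raise ValidationError(f"duplicate gene_id across blocks: {dup!r}")
    conditions: list[str] = []
    for m in models:
        conditions += [c for c in m.conditions if c not in conditions]
    mult = pd.concat(
        [m.multipliers.reindex(columns=conditions, fill_value=1.0) for m in models]
    )
    return ExpressionModel(genes, mult, ref)


@dataclass
class GroundTruthCells:
    """True per-cell, per-gene molecule counts with cell labels.

    ``counts`` is dense cells x genes (int64); rows align with ``cell_ids``
    and the parallel ``conditions`` / ``cell_types`` labels.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    conditions: np.ndarray
    cell_types: np.ndarray
    rng_seed: int

    def __post_init__(self):
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("counts shape must be (n_cells, n_genes)")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_long(self) -> pd.DataFrame:
        """Tidy nonzero table: cell_id, gene_id, count."""
        rows, cols = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids[rows],
                "gene_id": self.gene_ids[cols],
                "count": self.counts[rows, cols],
            }
        )


def sample_cells(
    model: ExpressionModel,
    n_cells_per_condition: int,
    conditions: Sequence[str] | None = None,
    seed: int = 0,
    cell_type: str = "cell",
) -> GroundTruthCells:
    """Draw per-cell molecule counts from the model's negative binomial.

    Counts for gene g in condition c are NB with mean
    ``mean_molecules[g] * multiplier[g, c]`` and the model's dispersion
    (variance ``mu + mu^2 / dispersion``); infinite dispersion switches to
    Poisson.  Zero-mean (absent) genes are identically zero.
    """
    if n_cells_per_condition < 1:
        raise ValidationError("n_cells_per_condition must be >= 1")
    conditions = list(conditions) if conditions is not None else model.conditions
    unknown = [c for c in conditions if c not in model.multipliers.columns]
    if unknown:
        raise ValidationError(f"undeclared conditions: {unknown}")
    rng = np.random.default_rng(seed)
    base = model.genes["mean_molecules"].to_numpy()
    theta = model.genes["dispersion"].to_numpy()
    blocks, cond_labels, cell_ids = [], [], []
    for cond in conditions:
        mu = base * model.multipliers[cond].to_numpy()
        shape = (n_cells_per_condition, len(mu))
        counts = np.zeros(shape, dtype=np.int64)
        pos = mu > 0
        if pos.any():
            mu_p, th_p = mu[pos], theta[pos]
            poisson = ~np.isfinite(th_p)
            out = np.empty((n_cells_per_condition, pos.sum()), dtype=np.int64)
            if poisson.any():
                out[:, poisson] = rng.poisson(mu_p[poisson], (n_cells_per_condition, int(poisson.sum())))
            nb = ~poisson
            if nb.any():
                p = th_p[nb] / (th_p[nb] + mu_p[nb])
                out[:, nb] = rng.negative_binomial(
                    th_p[nb], p, (n_cells_per_condition, int(nb.sum()))
                )
            counts[:, pos] = out
        blocks.append(counts)
        cond_labels += [cond] * n_cells_per_condition
        cell_ids += [f"{cond}_{i:05d}" for i in range(n_cells_per_condition)]
    return GroundTruthCells(
        counts=np.vstack(blocks),
        cell_ids=np.array(cell_ids),
        gene_ids=model.gene_ids.astype(str),
        conditions=np.array(cond_labels),
        cell_types=np.full(len(cell_ids), cell_type),
        rng_seed=int(seed),
    )


_BASES = np.array(list("ACGT"))


def index_to_barcode(index: int, length: int = 12) -> str:
    """Deterministic unique cell barcode: base-4 expansion of the cell index."""
    digits = []
    x = int(index)
    for _ in range(length):
        digits.append(x % 4)
        x //= 4
    return "".join(_BASES[d] for d in reversed(digits))


def capture_molecules(
    cells: GroundTruthCells,
    capture_rate: float,
    umi_length: int = 8,
    barcode_length: int = 12,
    seed: int = 0,
) -> MoleculePool:
    """Bead capture: each true molecule kept i.i.d. with ``capture_rate``.

    Capture is probe-excess, so losses are a per-molecule Bernoulli event.
    Every captured molecule gets its cell's (unique) barcode and a UMI drawn
    uniformly from the ``4**umi_length`` sequence space; UMI collisions are
    permitted and never corrected.  All records start at one copy and are not
    yet sequencing-eligible (no library adapter before amplification).
    """
    if not 0.0 <= capture_rate <= 1.0:
        raise ValidationError("capture_rate must be in [0, 1]")
    if umi_length < 1 or umi_length > 30:
        raise ValidationError("umi_length must be in [1, 30]")
    if 4**barcode_length < cells.n_cells:
        raise ValidationError("barcode_length too short to give every cell a unique barcode")
    rng = np.random.default_rng(seed)
    captured = rng.binomial(cells.counts, capture_rate)
    rows, cols = np.nonzero(captured)
    reps = captured[rows, cols]
    cell_idx = np.repeat(rows, reps).astype(np.int64)
    gene_idx = np.repeat(cols, reps).astype(np.int64)
    n = len(cell_idx)
    umi = rng.integers(0, 4**umi_length, size=n, dtype=np.int64)
    barcodes = np.array([index_to_barcode(i, barcode_length) for i in range(cells.n_cells)])
    return MoleculePool(
        cell=cell_idx,
        gene=gene_idx,
        umi=umi,
        copies=np.ones(n, dtype=np.int64),
        eligible=np.zeros(n, dtype=bool),
        cell_ids=barcodes,
        gene_ids=cells.gene_ids.astype(str),
        umi_length=int(umi_length),
    )
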