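"""Library-level sparsity and sensitivity statistics on read sets.

The quantities here are the standard droplet-QC vocabulary: UMI
deduplication (distinct (cell, UMI, gene) triples), per-cell duplication
rate (gene-assigned reads over distinct UMIs — the share of the read
budget burnt on amplified copies), per-gene dropout fractions and
detection at a dropout cut-off, the on-target read fraction of a targeted
panel, exact per-cell read downsampling for depth-titration curves, the
per-gene sensitivity fold between two libraries, and a simple cell QC
filter.  Count matrices are :class:`anndata.AnnData` objects, cells x
genes, with sparse integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ampsim import ReadSet
from .errors import ValidationError
from .paneldesign import GenePanel

__all__ = [
    "deduplicate",
    "duplication_rate",
    "dropout_profile",
    "detected_genes",
    "on_target_fraction",
    "downsample_reads",
    "sensitivity_fold",
    "cell_qc_filter",
    "BenchmarkReport",
    "build_report",
]


def _triple_keys(reads: ReadSet) -> tuple[np.ndarray, int]:
    """Encode (cell, gene, umi) into one int64 key per read; returns (keys, umi_space)."""
    n_genes = len(reads.gene_ids)
    umi_space = 4**reads.umi_length
    if len(reads.cell_ids) * n_genes * umi_space >= 2**62:
        raise ValidationError(
            "cell x gene x UMI space too large for int64 keys; reduce umi_length"
        )
    pair = reads.cell.astype(np.int64) * n_genes + reads.gene
    return pair * umi_space + reads.umi, umi_space


def deduplicate(reads: ReadSet) -> ad.AnnData:
    """Collapse reads to UMI counts: count of gene g in cell c is the number
    of distinct (c, g, umi) triples observed.

    Returns an AnnData over the read set's full cell and gene universe (cells
    with zero reads appear as zero rows) with ``obs['total_reads']`` and
    ``obs['total_umis']`` filled in.
    """
    n_cells, n_genes = len(reads.cell_ids), len(reads.gene_ids)
    if reads.n_reads:
        keys, umi_space = _triple_keys(reads)
        uniq = np.unique(keys)
        pair = uniq // umi_space
        pair_uniq, pair_counts = np.unique(pair, return_counts=True)
        rows = (pair_uniq // n_genes).astype(np.int64)
        cols = (pair_uniq % n_genes).astype(np.int64)
        X = sp.csr_matrix(
            (pair_counts.astype(np.int64), (rows, cols)), shape=(n_cells, n_genes)
        )
    else:
        X = sp.csr_matrix((n_cells, n_genes), dtype=np.int64)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(reads.cell_ids.astype(str), name="cell_barcode")),
        var=pd.DataFrame(index=pd.Index(reads.gene_ids.astype(str), name="gene_id")),
    )
    adata.obs["total_reads"] = reads.reads_per_cell()
    adata.obs["total_umis"] = np.asarray(X.sum(axis=1)).ravel().astype(np.int64)
    adata.uns["umi_length"] = reads.umi_length
    adata.uns["read_budget"] = reads.read_budget
    return adata


def duplication_rate(reads: ReadSet, counts: ad.AnnData) -> pd.Series:
    """Per-cell gene-assigned reads divided by distinct UMIs.

    1.0 means every read hit a new molecule; large values mean the budget was
    spent re-reading amplified copies.  Cells with zero UMIs get NaN (flagged
    undefined rather than dropped).
    """
    if list(counts.obs_names) != [str(c) for c in reads.cell_ids]:
        raise ValidationError("counts and reads disagree on the cell universe")
    r = reads.reads_per_cell().astype(float)
    u = counts.obs["total_umis"].to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(u > 0, r / u, np.nan)
    return pd.Series(rate, index=counts.obs_names, name="duplication_rate")


def dropout_profile(counts: ad.AnnData, genes=None) -> pd.Series:
    """Per-gene fraction of cells with zero count."""
    if counts.n_obs < 1:
        raise ValidationError("dropout requires at least one cell")
    sub = counts[:, list(genes)] if genes is not None else counts
    nnz = np.asarray((sub.X > 0).sum(axis=0)).ravel()
    return pd.Series(1.0 - nnz / sub.n_obs, index=sub.var_names, name="dropout_fraction")


def detected_genes(
    counts: ad.AnnData, dropout_cutoff: float = 0.5, genes=None
) -> tuple[list[str], int]:
    """Genes whose dropout fraction is at or below the cut-off.

    The boundary is inclusive: a gene seen in exactly half the cells at a 0.5
    cut-off counts as detected.  Returns (gene list, cardinality).
    """
    if not 0.0 < dropout_cutoff < 1.0:
        raise ValidationError("dropout_cutoff must lie strictly between 0 and 1")
    prof = dropout_profile(counts, genes)
    hit = prof.index[prof <= dropout_cutoff].tolist()
    return hit, len(hit)


def on_target_fraction(reads: ReadSet, panel: GenePanel) -> float:
    """Share of reads assigned to panel genes — the read-space efficiency of
    the targeted library."""
    if reads.n_reads == 0:
        raise ValidationError("on_target_fraction is undefined for an empty read set")
    on = np.isin(reads.gene_ids, list(panel.gene_ids))
    return float(on[reads.gene].sum() / reads.n_reads)


def downsample_reads(reads: ReadSet, depth_per_cell: int, seed: int) -> ReadSet:
    """Exact per-cell thinning to ``depth_per_cell`` reads without replacement.

    Mirrors a "reads per bead" depth ladder: every cell holding at least the
    requested depth keeps exactly that many uniformly chosen reads; shallower
    cells keep everything and are flagged in ``underfilled_cells``.
    """
    if depth_per_cell < 1:
        raise ValidationError("depth_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(reads.n_reads)
    order = np.lexsort((u, reads.cell))
    cell_sorted = reads.cell[order]
    # rank of each read within its cell after random shuffling
    starts = np.searchsorted(cell_sorted, np.arange(reads.n_cells))
    rank = np.arange(reads.n_reads) - starts[cell_sorted]
    keep = order[rank < depth_per_cell]
    keep.sort()  # preserve original read order
    per_cell = reads.reads_per_cell()
    short = np.nonzero(per_cell < depth_per_cell)[0]
    return ReadSet(
        cell=reads.cell[keep],
        gene=reads.gene[keep],
        umi=reads.umi[keep],
        cell_ids=reads.cell_ids,
        gene_ids=reads.gene_ids,
        umi_length=reads.umi_length,
        read_budget=depth_per_cell,
        underfilled_cells=short.astype(np.int64),
    )


def sensitivity_fold(
    counts_a: ad.AnnData,
    counts_b: ad.AnnData,
    genes=None,
    eps: float = 0.0,
) -> tuple[pd.DataFrame, float]:
    """Per-gene mean-count ratio a/b and its geometric-mean summary.

    For each shared gene the fold is ``(mean_a + eps) / (mean_b + eps)``.
    With the default ``eps = 0``, genes absent from both matrices are flagged
    undefined (NaN), and genes with a zero denominator are excluded from the
    summary (their fold is +inf); the summary is the geometric mean over genes
    expressed in at least one library with a finite fold.
    """
    if counts_a.n_obs == 0 or counts_b.n_obs == 0:
        raise ValidationError("both count matrices must contain cells")
    shared = (
        [g for g in genes if g in counts_a.var_names and g in counts_b.var_names]
        if genes is not None
        else [g for g in counts_a.var_names if g in set(counts_b.var_names)]
    )
    if not shared:
        raise ValidationError("no shared genes between the two count matrices")
    ma = np.asarray(counts_a[:, shared].X.mean(axis=0)).ravel()
    mb = np.asarray(counts_b[:, shared].X.mean(axis=0)).ravel()
    num, den = ma + eps, mb + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(den > 0, num / den, np.where(num > 0, np.inf, np.nan))
    expressed = (ma > 0) | (mb > 0)
    in_summary = expressed & np.isfinite(fold) & (fold > 0)
    table = pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "fold": fold,
            "defined": ~np.isnan(fold),
            "in_summary": in_summary,
        },
        index=pd.Index(shared, name="gene_id"),
    )
    summary = (
        float(np.exp(np.mean(np.log(fold[in_summary])))) if in_summary.any() else float("nan")
    )
    return table, summary


def cell_qc_filter(
    counts: ad.AnnData, min_umis: int = 200, min_genes: int = 3
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Keep cells with enough total UMIs and detected genes; log removals.

    The default thresholds (200 UMIs, 3 genes) are conventions sized for
    targeted panels, not universal constants.
    """
    if min_umis < 0 or min_genes < 0:
        raise ValidationError("QC thresholds must be nonnegative")
    total = np.asarray(counts.X.sum(axis=1)).ravel()
    ngene = np.asarray((counts.X > 0).sum(axis=1)).ravel()
    keep = (total >= min_umis) & (ngene >= min_genes)
    reasons = []
    for i in np.nonzero(~keep)[0]:
        why = []
        if total[i] < min_umis:
            why.append(f"umis {int(total[i])} < {min_umis}")
        if ngene[i] < min_genes:
            why.append(f"genes {int(ngene[i])} < {min_genes}")
        reasons.append((counts.obs_names[i], int(total[i]), int(ngene[i]), "; ".join(why)))
    log = pd.DataFrame(reasons, columns=["cell_barcode", "total_umis", "n_genes", "reason"])
    return counts[keep].copy(), log


@dataclass
class BenchmarkReport:
    """Per-gene, per-cell and library-level metrics for one sequencing run."""

    per_gene: pd.DataFrame
    per_cell: pd.DataFrame
    library: dict

    def summary(self) -> dict:
        return dict(self.library)


def build_report(
    reads: ReadSet,
    panel: GenePanel,
    dropout_cutoff: float = 0.5,
    counts: ad.AnnData | None = None,
) -> BenchmarkReport:
    """Assemble the standard benchmark report for one read set.

    Detection at the cut-off is evaluated over panel genes; negative-control
    detections are reported separately in the library block.
    """
    if counts is None:
        counts = deduplicate(reads)
    panel_genes = [g for g in panel.gene_ids if g in set(counts.var_names)]
    dup = duplication_rate(reads, counts)
    dropout = dropout_profile(counts)
    detected, n_detected = detected_genes(counts, dropout_cutoff, genes=panel_genes)
    mean_count = np.asarray(counts.X.mean(axis=0)).ravel()
    per_gene = pd.DataFrame(
        {
            "mean_count": mean_count,
            "dropout_fraction": dropout.to_numpy(),
            "detected": (dropout <= dropout_cutoff).to_numpy(),
            "on_panel": counts.var_names.isin(panel_genes),
            "negative_control": [panel.is_negative_control(g) for g in counts.var_names],
        },
        index=counts.var_names.copy(),
    )
    per_cell = pd.DataFrame(
        {
            "reads": counts.obs["total_reads"].to_numpy(),
            "umis": counts.obs["total_umis"].to_numpy(),
            "duplication_rate": dup.to_numpy(),
        },
        index=counts.obs_names.copy(),
    )
    neg_detected = [g for g in detected if panel.is_negative_control(g)]
    library = {
        "on_target_fraction": on_target_fraction(reads, panel),
        "n_detected_at_cutoff": n_detected - len(neg_detected),
        "n_negative_controls_detected": len(neg_detected),
        "dropout_cutoff": dropout_cutoff,
        "median_duplication_rate": float(np.nanmedian(dup.to_numpy())),
        "median_umis_per_cell": float(np.median(per_cell["umis"])),
        "read_budget": reads.read_budget,
    }
    return BenchmarkReport(per_gene=per_gene, per_cell=per_cell, library=library)
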