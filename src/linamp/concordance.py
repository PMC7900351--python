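"""Pseudo-bulk fold-change concordance between two library methods.

Given two-condition single-cell counts from each method, the comparison
is made bulk-style: counts are summed per (gene, group), normalised to
counts per ten thousand (CPTT) so groups are depth-comparable, converted
to per-gene log2 fold changes between conditions with a pseudocount, and
the two methods' fold-change vectors are compared by Pearson correlation
and an ordinary least-squares fit.  The OLS slope of the targeted method
regressed on the standard one is the sensitivity readout: a slope above 1
means the targeted library reports larger expression shifts for the same
underlying perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PseudobulkTable",
    "ConcordanceResult",
    "pseudobulk",
    "normalize_cptt",
    "log_fold_change",
    "fc_concordance",
]


@dataclass
class PseudobulkTable:
    """Gene x group summed counts plus per-group library sizes."""

    table: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self):
        sums = self.table.sum(axis=0)
        if not np.array_equal(sums.to_numpy(), self.library_sizes.to_numpy()):
            raise ValidationError("library sizes must equal the column sums exactly")


def pseudobulk(counts: ad.AnnData, grouping) -> PseudobulkTable:
    """Sum single-cell counts per (gene, group); exact integer arithmetic.

    ``grouping`` is either the name of an ``obs`` column or a mapping /
    Series from cell barcode to group label.  Every cell must map to exactly
    one group.
    """
    if isinstance(grouping, str):
        if grouping not in counts.obs.columns:
            raise ValidationError(f"obs column {grouping!r} not found")
        labels = counts.obs[grouping].astype(str)
    else:
        mapping = dict(grouping) if isinstance(grouping, Mapping) else dict(pd.Series(grouping))
        missing = [c for c in counts.obs_names if c not in mapping]
        if missing:
            raise ValidationError(f"{len(missing)} cells unmapped to a group: {missing[:5]}")
        labels = pd.Series([str(mapping[c]) for c in counts.obs_names], index=counts.obs_names)
    groups = sorted(labels.unique())
    cols = {}
    X = counts.X
    for g in groups:
        mask = (labels == g).to_numpy()
        cols[g] = np.asarray(X[mask].sum(axis=0)).ravel().astype(np.int64)
    table = pd.DataFrame(cols, index=counts.var_names.copy())
    return PseudobulkTable(table=table, library_sizes=table.sum(axis=0))


def normalize_cptt(table):
    """Counts per ten thousand: scale each column so it sums to 10,000.

    Accepts a genes x groups DataFrame (pseudo-bulk) or an AnnData, in which
    case each cell (row) is scaled instead.  A zero-total column/cell is an
    error naming the offender, since its expression profile is undefined.
    """
    if isinstance(table, ad.AnnData):
        totals = np.asarray(table.X.sum(axis=1)).ravel()
        zero = np.nonzero(totals == 0)[0]
        if len(zero):
            raise ValidationError(f"cell {table.obs_names[zero[0]]!r} has zero total counts")
        out = table.copy()
        X = np.asarray(table.X.todense()) if hasattr(table.X, "todense") else np.asarray(table.X)
        out.X = X * (10_000.0 / totals)[:, None]
        return out
    totals = table.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"column {zero[0]!r} has zero total counts")
    return table * (10_000.0 / totals)


def log_fold_change(
    pb_cptt: pd.DataFrame, cond_a: str, cond_b: str, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((cptt_a + pc) / (cptt_b + pc)) on a CPTT-normalised table."""
    for c in (cond_a, cond_b):
        if c not in pb_cptt.columns:
            raise ValidationError(f"group {c!r} missing from the pseudo-bulk table")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return pd.Series(
        np.log2((pb_cptt[cond_a] + pseudocount) / (pb_cptt[cond_b] + pseudocount)),
        index=pb_cptt.index,
        name=f"log2fc_{cond_a}_vs_{cond_b}",
    )


@dataclass
class ConcordanceResult:
    """Cross-method agreement of per-gene fold changes."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n_genes: int
    genes: list[str]

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_genes": self.n_genes,
        }


def fc_concordance(
    fc_targeted: pd.Series, fc_standard: pd.Series, method: str = "ols"
) -> ConcordanceResult:
    """Pearson correlation and regression of targeted on standard fold changes.

    Genes undefined (NaN/inf) in either vector are dropped pairwise.  The
    default regression is OLS with intercept; ``method='major_axis'`` uses
    the geometric-mean (reduced major axis) slope instead, which treats both
    methods' noise symmetrically.
    """
    shared = fc_targeted.index.intersection(fc_standard.index)
    x = fc_standard.loc[shared].to_numpy(dtype=float)
    y = fc_targeted.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    genes = list(shared[ok])
    if len(x) < 3:
        raise ValidationError(f"need >= 3 genes with defined fold changes, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero-variance fold-change vector")
    r, p = stats.pearsonr(x, y)
    if method == "ols":
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif method == "major_axis":
        slope = float(np.sign(np.cov(x, y)[0, 1]) * np.std(y, ddof=1) / np.std(x, ddof=1))
        intercept = float(np.mean(y) - slope * np.mean(x))
    else:
        raise ValidationError(f"unknown regression method {method!r}")
    return ConcordanceResult(
        r=float(r), p_value=float(p), slope=slope, intercept=intercept,
        n_genes=len(x), genes=genes,
    )
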