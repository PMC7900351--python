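"""End-to-end orchestration of the two headline comparisons.

``run_sparsity_benchmark`` puts one shared ground truth through both
amplification regimes at a matched read budget and measures duplication
rate, UMIs per cell, on-target fraction, per-gene sensitivity folds and
panel detection across a downsampling depth ladder.

``run_stimulation_concordance`` simulates a two-condition perturbation,
runs both regimes, and compares pseudo-bulk CPTT log2 fold changes:
cross-regime concordance (correlation and OLS slope) and each regime's
recovery of the true fold effects.

Both derive every stage seed deterministically from the config's master
seed, keep a structured log of stages, and can persist all artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import io as lio
from ._util import child_seed
from .ampsim import (
    AmplificationParams,
    ReadSet,
    amplify_exponential,
    amplify_linear,
    sample_reads,
)
from .concordance import (
    ConcordanceResult,
    fc_concordance,
    log_fold_change,
    normalize_cptt,
    pseudobulk,
)
from .config import RunConfig
from .errors import ValidationError
from .groundtruth import (
    ExpressionModel,
    GroundTruthCells,
    build_expression_model,
    capture_molecules,
    concat_models,
    sample_cells,
)
from .libmetrics import (
    BenchmarkReport,
    build_report,
    deduplicate,
    detected_genes,
    downsample_reads,
    sensitivity_fold,
)
from .paneldesign import GenePanel, random_panel

__all__ = [
    "build_panel_model",
    "build_study",
    "run_sparsity_benchmark",
    "run_stimulation_concordance",
    "run_demo",
    "SparsityBenchmark",
    "StimulationConcordance",
]

REGIMES = ("linear", "exponential")


def _stage(log: list, stage: str, seed: int | None, **info) -> None:
    log.append({"stage": stage, "seed": seed, **info})


def build_panel_model(
    n_panel_genes: int,
    n_negative_controls: int,
    tier_fractions: dict,
    tier_means: dict,
    dispersion: float,
    seed: int,
    prefix: str = "T",
) -> ExpressionModel:
    """Expression model for a targeted panel whose last ``n_negative_controls``
    genes are absent-tier negative controls.

    Expressed genes split over the given tier fractions; control genes are
    named ``NC...`` so they are recognisable in reports.
    """
    neg_frac = n_negative_controls / n_panel_genes
    fractions = {t: f * (1.0 - neg_frac) for t, f in tier_fractions.items()}
    if n_negative_controls:
        fractions["absent"] = neg_frac
    n_expressed = n_panel_genes - n_negative_controls
    width = max(2, len(str(n_panel_genes)))
    ids = [f"{prefix}{i:0{width}d}" for i in range(1, n_expressed + 1)]
    ids += [f"NC{i:02d}" for i in range(1, n_negative_controls + 1)]
    return build_expression_model(
        n_panel_genes, fractions, tier_means, dispersion, seed, gene_ids=ids
    )


def build_study(config: RunConfig):
    """Shared ground truth for the sparsity benchmark: panel + background
    transcriptome model, synthetic compliant panel, cells and captured pool."""
    gt = config.groundtruth
    panel_model = build_panel_model(
        gt.n_panel_genes,
        gt.n_negative_controls,
        gt.panel_tier_fractions,
        gt.tier_means,
        gt.dispersion,
        child_seed(config.seed, "panel-model"),
    )
    if gt.n_background_genes:
        bg_model = build_expression_model(
            gt.n_background_genes,
            gt.background_tier_fractions,
            gt.tier_means,
            gt.dispersion,
            child_seed(config.seed, "background-model"),
            gene_ids=[f"BG{i:04d}" for i in range(1, gt.n_background_genes + 1)],
        )
        model = concat_models(panel_model, bg_model)
    else:
        model = panel_model
    panel = random_panel(
        panel_model.gene_ids.tolist(),
        negative_controls=[g for g in panel_model.gene_ids if str(g).startswith("NC")],
        seed=child_seed(config.seed, "panel-design"),
    )
    cells = sample_cells(model, gt.n_cells, seed=child_seed(config.seed, "cells"))
    pool = capture_molecules(
        cells,
        gt.capture_rate,
        gt.umi_length,
        gt.barcode_length,
        seed=child_seed(config.seed, "capture"),
    )
    return model, panel, cells, pool


def draw_efficiencies(model: ExpressionModel, efficiency_range, seed: int) -> dict:
    """Per-gene PCR efficiencies ~ Uniform(lo, hi): the sole driver of
    exponential amplification bias."""
    rng = np.random.default_rng(seed)
    lo, hi = efficiency_range
    return dict(zip(map(str, model.gene_ids), rng.uniform(lo, hi, len(model.gene_ids))))


def amplify_both_regimes(
    pool, panel: GenePanel, model: ExpressionModel, config: RunConfig, label: str = ""
) -> dict:
    """Amplify one captured pool under both regimes with config-derived seeds."""
    amp = config.amplification
    eff = draw_efficiencies(
        model, amp.efficiency_range, child_seed(config.seed, f"{label}efficiency")
    )
    exp_params = AmplificationParams(n_cycles=amp.n_cycles, efficiency=eff)
    lin_params = AmplificationParams(
        n_cycles=amp.n_cycles,
        priming_probability=amp.priming_probability,
        offtarget_rate=amp.offtarget_rate,
    )
    return {
        "linear": amplify_linear(
            pool, panel, lin_params, child_seed(config.seed, f"{label}amp-linear")
        ),
        "exponential": amplify_exponential(
            pool, exp_params, child_seed(config.seed, f"{label}amp-exponential")
        ),
    }


@dataclass
class SparsityBenchmark:
    """Everything the matched two-regime comparison produces."""

    reports: dict[str, BenchmarkReport]
    detection_by_depth: pd.DataFrame
    sensitivity_table: pd.DataFrame
    sensitivity_summary: float
    reads: dict[str, ReadSet]
    counts: dict[str, ad.AnnData]
    log: list = field(default_factory=list)

    def summary(self) -> dict:
        out = {r: self.reports[r].summary() for r in self.reports}
        out["sensitivity_fold_geometric_mean"] = self.sensitivity_summary
        return out


def run_sparsity_benchmark(config: RunConfig, out_dir=None) -> SparsityBenchmark:
    """One ground truth, two regimes, matched read budgets, depth ladder."""
    config.validate()
    log: list = []
    model, panel, cells, pool = build_study(config)
    _stage(log, "ground-truth", child_seed(config.seed, "cells"),
           params_hash=config.params_hash(), n_cells=cells.n_cells,
           n_genes=len(model.gene_ids), n_captured_molecules=pool.n_records)
    pools = amplify_both_regimes(pool, panel, model, config)
    budget = config.sequencing.read_budget_per_cell
    panel_targets = [g for g in panel.gene_ids if not panel.is_negative_control(g)]

    reads, counts, reports = {}, {}, {}
    rows = []
    for regime in REGIMES:
        rs = sample_reads(pools[regime], budget, child_seed(config.seed, f"reads-{regime}"))
        _stage(log, f"reads-{regime}", child_seed(config.seed, f"reads-{regime}"),
               n_reads=rs.n_reads)
        cm = deduplicate(rs)
        cm.obs["condition"] = cells.conditions
        cm.obs["cell_id"] = cells.cell_ids
        cm.var["on_panel"] = cm.var_names.isin(list(panel.gene_ids))
        cm.var["negative_control"] = [panel.is_negative_control(g) for g in cm.var_names]
        reads[regime], counts[regime] = rs, cm
        reports[regime] = build_report(rs, panel, config.metrics.dropout_cutoff, counts=cm)
        # nested ladder: each depth is a subsample of the one above, so a
        # gene's UMIs can only shrink with depth and detection is monotone
        ladder_rows = []
        ds = rs
        for depth in sorted(config.sequencing.depth_ladder, reverse=True):
            if depth < ds.read_budget:
                ds = downsample_reads(ds, depth, child_seed(config.seed, f"ds-{regime}-{depth}"))
            dcounts = deduplicate(ds)
            hit, _ = detected_genes(dcounts, config.metrics.dropout_cutoff, genes=panel_targets)
            neg_hit, _ = detected_genes(
                dcounts, config.metrics.dropout_cutoff,
                genes=[g for g in panel.gene_ids if panel.is_negative_control(g)],
            )
            ladder_rows.append(
                {
                    "regime": regime,
                    "depth": depth,
                    "n_detected": len(hit),
                    "n_negative_controls_detected": len(neg_hit),
                }
            )
        rows.extend(sorted(ladder_rows, key=lambda r: r["depth"]))
    detection = pd.DataFrame(rows)
    sens_table, sens_summary = sensitivity_fold(
        counts["linear"], counts["exponential"], genes=panel_targets
    )
    _stage(log, "sensitivity", None, geometric_mean_fold=sens_summary)
    result = SparsityBenchmark(
        reports=reports,
        detection_by_depth=detection,
        sensitivity_table=sens_table,
        sensitivity_summary=sens_summary,
        reads=reads,
        counts=counts,
        log=log,
    )
    if out_dir is not None:
        _write_sparsity(result, config, Path(out_dir))
    return result


def _write_sparsity(result: SparsityBenchmark, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for regime in REGIMES:
        lio.write_counts_mtx(result.counts[regime], out / f"counts_{regime}")
        result.reports[regime].per_gene.to_csv(out / f"per_gene_{regime}.csv")
        result.reports[regime].per_cell.to_csv(out / f"per_cell_{regime}.csv")
    result.detection_by_depth.to_csv(out / "detection_by_depth.csv", index=False)
    result.sensitivity_table.to_csv(out / "sensitivity_fold.csv")
    (out / "summary.json").write_text(json.dumps(result.summary(), indent=2, default=float))
    config.to_yaml(out / "config.yaml")
    with open(out / "run_log.jsonl", "w") as fh:
        for rec in result.log:
            fh.write(json.dumps(rec, default=float) + "\n")


@dataclass
class StimulationConcordance:
    """Fold-change tables and concordance fits for the two-condition design."""

    truth_log2fc: pd.Series
    fc: dict[str, pd.Series]
    cross_regime: ConcordanceResult
    vs_truth: dict[str, ConcordanceResult]
    pseudobulk: dict[str, pd.DataFrame]
    counts: dict[str, ad.AnnData]
    log: list = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "cross_regime": self.cross_regime.to_dict(),
            "vs_truth": {k: v.to_dict() for k, v in self.vs_truth.items()},
        }


def build_stimulation_study(config: RunConfig):
    """Two-condition ground truth: panel genes carry known log2 fold effects."""
    stim = config.stimulation
    gt = config.groundtruth
    if len(stim.conditions) < 2:
        raise ValidationError("stimulation requires at least two conditions")
    panel_model = build_panel_model(
        stim.n_panel_genes,
        0,
        {"medium": 1.0},
        {"medium": stim.panel_tier_mean},
        gt.dispersion,
        child_seed(config.seed, "stim-panel-model"),
    )
    # one declared log2 effect per panel gene (balanced design, see config)
    effects = {
        str(g): float(2.0 ** stim.log2_effects[i])
        for i, g in enumerate(panel_model.gene_ids)
    }
    stim_cond = stim.conditions[1]
    panel_model = panel_model.with_condition_effect(stim_cond, effects)
    bg_model = build_expression_model(
        stim.n_background_genes,
        gt.background_tier_fractions,
        gt.tier_means,
        gt.dispersion,
        child_seed(config.seed, "stim-background-model"),
        gene_ids=[f"BG{i:04d}" for i in range(1, stim.n_background_genes + 1)],
    ).with_condition_effect(stim_cond, {})
    model = concat_models(panel_model, bg_model)
    panel = random_panel(
        panel_model.gene_ids.tolist(), seed=child_seed(config.seed, "stim-panel-design")
    )
    cells = sample_cells(
        model,
        stim.n_cells_per_condition,
        conditions=list(stim.conditions),
        seed=child_seed(config.seed, "stim-cells"),
    )
    pool = capture_molecules(
        cells, gt.capture_rate, gt.umi_length, gt.barcode_length,
        seed=child_seed(config.seed, "stim-capture"),
    )
    truth = pd.Series(
        {g: float(np.log2(effects[g])) for g in map(str, panel_model.gene_ids)},
        name="true_log2fc",
    )
    return model, panel, cells, pool, truth


def run_stimulation_concordance(config: RunConfig, out_dir=None) -> StimulationConcordance:
    """Simulate both conditions under both regimes and compare pseudo-bulk
    CPTT fold changes across regimes and against the true effects."""
    config.validate()
    stim = config.stimulation
    log: list = []
    model, panel, cells, pool, truth = build_stimulation_study(config)
    _stage(log, "stim-ground-truth", child_seed(config.seed, "stim-cells"),
           params_hash=config.params_hash(), n_cells=cells.n_cells,
           n_captured_molecules=pool.n_records)
    pools = amplify_both_regimes(pool, panel, model, config, label="stim-")
    cond_ref, cond_stim = stim.conditions[0], stim.conditions[1]
    panel_genes = list(panel.gene_ids)
    fc, pbs, counts = {}, {}, {}
    for regime in REGIMES:
        rs = sample_reads(
            pools[regime],
            stim.read_budget_per_cell,
            child_seed(config.seed, f"stim-reads-{regime}"),
        )
        cm = deduplicate(rs)
        cm.obs["condition"] = cells.conditions
        counts[regime] = cm
        pb = pseudobulk(cm, "condition")
        cptt = normalize_cptt(pb.table)
        pbs[regime] = pb.table
        fc[regime] = log_fold_change(cptt, cond_stim, cond_ref, stim.pseudocount).loc[
            panel_genes
        ]
        _stage(log, f"stim-fc-{regime}", child_seed(config.seed, f"stim-reads-{regime}"),
               n_reads=rs.n_reads)
    cross = fc_concordance(fc["linear"], fc["exponential"])
    if truth.nunique() > 1:
        vs_truth = {r: fc_concordance(fc[r], truth) for r in REGIMES}
    else:
        # a null design (all effects equal) leaves nothing to regress against
        vs_truth = {}
    result = StimulationConcordance(
        truth_log2fc=truth,
        fc=fc,
        cross_regime=cross,
        vs_truth=vs_truth,
        pseudobulk=pbs,
        counts=counts,
        log=log,
    )
    if out_dir is not None:
        _write_stimulation(result, config, Path(out_dir))
    return result


def _write_stimulation(result: StimulationConcordance, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({"true_log2fc": result.truth_log2fc})
    for regime in REGIMES:
        table[f"log2fc_{regime}"] = result.fc[regime]
        result.pseudobulk[regime].to_csv(out / f"pseudobulk_{regime}.csv")
        lio.write_counts_mtx(result.counts[regime], out / f"counts_{regime}")
    table.to_csv(out / "fold_changes.csv")
    (out / "concordance.json").write_text(
        json.dumps(result.summary(), indent=2, default=float)
    )
    config.to_yaml(out / "config.yaml")
    with open(out / "run_log.jsonl", "w") as fh:
        for rec in result.log:
            fh.write(json.dumps(rec, default=float) + "\n")


def run_demo(out_dir, seed: int = 0) -> dict:
    """Both headline experiments at the default study conditions."""
    config = RunConfig(seed=seed)
    out = Path(out_dir)
    sparsity = run_sparsity_benchmark(config, out / "sparsity")
    stim = run_stimulation_concordance(config, out / "stimulation")
    return {"sparsity": sparsity.summary(), "stimulation": stim.summary()}
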