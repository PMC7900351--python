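"""Matched comparison of linear-targeted vs exponential library prep.

One shared ground truth (52-gene panel with 3 negative controls over a
background transcriptome) is amplified under both regimes and sequenced at
the same budget; the benchmark reports duplication rates, on-target read
fractions, per-gene sensitivity folds, and panel detection at a 50%
dropout cut-off across a nested read-depth ladder.  Sizes are scaled down
here so the example runs in seconds; defaults reproduce the full study.
"""

from linamp import run_sparsity_benchmark
from linamp.config import GroundTruthConfig, RunConfig, SequencingConfig

config = RunConfig(seed=1)
config.groundtruth = GroundTruthConfig(n_background_genes=300, n_cells=50)
config.sequencing = SequencingConfig(
    read_budget_per_cell=8_000, depth_ladder=(2_000, 4_000, 8_000)
)
result = run_sparsity_benchmark(config)

for regime in ("linear", "exponential"):
    lib = result.reports[regime].library
    print(
        f"{regime:>12}: on-target {lib['on_target_fraction']:.1%}, "
        f"median dup rate {lib['median_duplication_rate']:.2f}, "
        f"median UMIs/cell {lib['median_umis_per_cell']:.0f}, "
        f"{lib['n_detected_at_cutoff']}/49 panel genes detected"
    )
print(f"sensitivity fold (geometric mean over panel): "
      f"{result.sensitivity_summary:.2f}x")
print("\ndetection vs depth (50% dropout cut-off):")
print(result.detection_by_depth.to_string(index=False))
print("-> the targeted library spends its reads on the panel, so detection")
print("   saturates at a fraction of the depth the standard library needs.")
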