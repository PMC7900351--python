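"""Two-condition perturbation: do both library methods report the same fold
changes, and how faithfully is the true effect recovered?

Panel genes carry known log2 fold effects between a control and a
stimulated condition.  Both regimes are simulated on the same cells;
pseudo-bulk counts are CPTT-normalised and per-gene log2 fold changes are
compared across regimes and against the truth (Pearson r, OLS slope).
"""

import pandas as pd

from linamp import run_stimulation_concordance
from linamp.config import RunConfig, StimulationConfig

config = RunConfig(seed=5)
config.stimulation = StimulationConfig(
    n_panel_genes=10,
    n_background_genes=50,
    log2_effects=(2.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -1.0, -2.0),
    n_cells_per_condition=150,
    read_budget_per_cell=5_000,
)
result = run_stimulation_concordance(config)

table = pd.DataFrame(
    {
        "truth": result.truth_log2fc,
        "linear": result.fc["linear"],
        "exponential": result.fc["exponential"],
    }
).round(2)
print("per-gene log2 fold changes (stim vs control):")
print(table.to_string())
cross = result.cross_regime
print(f"\ncross-regime concordance: r = {cross.r:.2f} "
      f"(p = {cross.p_value:.1e}), slope = {cross.slope:.2f}")
for regime, fit in result.vs_truth.items():
    print(f"{regime} vs truth: r = {fit.r:.2f}, slope = {fit.slope:.2f}")
print("-> slope ~ 1 against truth means the perturbation response is")
print("   recovered without inflation; cross-regime r shows both methods")
print("   read out the same biology.")
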