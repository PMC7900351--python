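"""Run configuration: one structured object fully determines every output.

The defaults encode the package's reference study conditions: a 52-gene
targeted panel with 3 absent-tier negative controls over a background
transcriptome, abundance-tier molecule means, droplet capture, 12
amplification cycles in both regimes, a 15k reads/cell budget with a
2k/4k/8k/15k downsampling ladder, and a two-condition stimulation design
(20-gene panel, log2 effects -2..2, 500 cells per condition at 20k
reads/cell).  Every stochastic stage derives its own seed from the single
master ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = [
    "GroundTruthConfig",
    "AmplificationConfig",
    "SequencingConfig",
    "MetricsConfig",
    "StimulationConfig",
    "RunConfig",
]


@dataclass
class GroundTruthConfig:
    """Panel composition, abundance tiers, capture and barcode/UMI geometry."""

    n_panel_genes: int = 52
    n_negative_controls: int = 3
    panel_tier_fractions: dict = field(
        default_factory=lambda: {"high": 0.2, "medium": 0.3, "low": 0.5}
    )
    n_background_genes: int = 1000
    background_tier_fractions: dict = field(
        default_factory=lambda: {"high": 0.05, "medium": 0.25, "low": 0.7}
    )
    tier_means: dict = field(
        default_factory=lambda: {"high": 1000.0, "medium": 300.0, "low": 80.0}
    )
    dispersion: float = 2.0
    n_cells: int = 200
    capture_rate: float = 0.1
    umi_length: int = 8
    barcode_length: int = 12

    def validate(self) -> list[str]:
        errs = []
        if self.n_panel_genes < 1:
            errs.append("groundtruth.n_panel_genes must be >= 1")
        if not 0 <= self.n_negative_controls < self.n_panel_genes:
            errs.append("groundtruth.n_negative_controls must be in [0, n_panel_genes)")
        if not 0.0 <= self.capture_rate <= 1.0:
            errs.append("groundtruth.capture_rate must be in [0, 1]")
        if self.n_cells < 1:
            errs.append("groundtruth.n_cells must be >= 1")
        if self.umi_length < 1:
            errs.append("groundtruth.umi_length must be >= 1")
        if self.dispersion <= 0:
            errs.append("groundtruth.dispersion must be positive")
        return errs


@dataclass
class AmplificationConfig:
    """Cycle counts and priming probabilities for both regimes."""

    n_cycles: int = 12
    priming_probability: float = 0.8
    offtarget_rate: float = 0.01
    efficiency_range: tuple = (0.7, 0.95)

    def validate(self) -> list[str]:
        errs = []
        if self.n_cycles < 1:
            errs.append("amplification.n_cycles must be >= 1")
        for name in ("priming_probability", "offtarget_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"amplification.{name} must be in [0, 1]")
        lo, hi = self.efficiency_range
        if not (0.0 <= lo <= hi <= 1.0):
            errs.append("amplification.efficiency_range must satisfy 0 <= lo <= hi <= 1")
        return errs


@dataclass
class SequencingConfig:
    """Per-cell read budget and the depth-titration ladder."""

    read_budget_per_cell: int = 15_000
    depth_ladder: tuple = (2_000, 4_000, 8_000, 15_000)

    def validate(self) -> list[str]:
        errs = []
        if self.read_budget_per_cell < 1:
            errs.append("sequencing.read_budget_per_cell must be >= 1")
        if any(d < 1 for d in self.depth_ladder):
            errs.append("sequencing.depth_ladder entries must be >= 1")
        if any(d > self.read_budget_per_cell for d in self.depth_ladder):
            errs.append("sequencing.depth_ladder entries must not exceed the read budget")
        return errs


@dataclass
class MetricsConfig:
    """Detection cut-off and cell QC thresholds."""

    dropout_cutoff: float = 0.5
    min_umis: int = 200
    min_genes: int = 3

    def validate(self) -> list[str]:
        errs = []
        if not 0.0 < self.dropout_cutoff < 1.0:
            errs.append("metrics.dropout_cutoff must lie strictly between 0 and 1")
        if self.min_umis < 0 or self.min_genes < 0:
            errs.append("metrics QC thresholds must be nonnegative")
        return errs


@dataclass
class StimulationConfig:
    """Two-condition perturbation design for the concordance experiment.

    ``log2_effects`` assigns each panel gene its true log2 fold effect.  The
    default covers effects in {-2, -1, 0, 1, 2} in a compositionally balanced
    mix (the expected total panel output is the same in both conditions, sum
    of fold multipliers ~ n genes): within a closed library, normalisation
    can only identify relative changes, so an unbalanced design would shift
    every null gene's apparent fold change.
    """

    n_panel_genes: int = 20
    n_background_genes: int = 100
    log2_effects: tuple = (
        2.0, 1.0, 1.0,
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
        -1.0, -1.0, -1.0, -1.0,
        -2.0, -2.0, -2.0,
    )
    conditions: tuple = ("control", "stim")
    n_cells_per_condition: int = 500
    read_budget_per_cell: int = 20_000
    pseudocount: float = 1.0
    panel_tier_mean: float = 300.0

    def validate(self) -> list[str]:
        errs = []
        if len(self.conditions) < 2:
            errs.append("stimulation.conditions must declare at least two conditions")
        if self.n_cells_per_condition < 1:
            errs.append("stimulation.n_cells_per_condition must be >= 1")
        if self.pseudocount <= 0:
            errs.append("stimulation.pseudocount must be positive")
        if self.n_panel_genes < 3:
            errs.append("stimulation.n_panel_genes must be >= 3 for a concordance fit")
        if len(self.log2_effects) != self.n_panel_genes:
            errs.append("stimulation.log2_effects must assign one effect per panel gene")
        return errs


@dataclass
class RunConfig:
    """Everything needed to reproduce a run byte-for-byte."""

    groundtruth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    amplification: AmplificationConfig = field(default_factory=AmplificationConfig)
    sequencing: SequencingConfig = field(default_factory=SequencingConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stimulation: StimulationConfig = field(default_factory=StimulationConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        """Aggregate all schema violations into one error before any compute."""
        errs = []
        for block in (
            self.groundtruth, self.amplification, self.sequencing, self.metrics,
            self.stimulation,
        ):
            errs.extend(block.validate())
        if errs:
            raise ValidationError("invalid configuration:\n  " + "\n  ".join(errs))
        return self

    def params_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        blocks = {
            "groundtruth": GroundTruthConfig,
            "amplification": AmplificationConfig,
            "sequencing": SequencingConfig,
            "metrics": MetricsConfig,
            "stimulation": StimulationConfig,
        }
        kwargs = {}
        unknown = set(raw) - set(blocks) - {"seed"}
        if unknown:
            raise ValidationError(f"unknown config sections: {sorted(unknown)}")
        for name, klass in blocks.items():
            sub = raw.get(name, {})
            bad = set(sub) - {f for f in klass.__dataclass_fields__}
            if bad:
                raise ValidationError(f"unknown keys in config section {name}: {sorted(bad)}")
            # YAML lists stand in for tuple-typed fields
            sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
            kwargs[name] = klass(**sub)
        return cls(seed=int(raw.get("seed", 0)), **kwargs).validate()
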