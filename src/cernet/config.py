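"""Threshold and pipeline configuration.

`ThresholdConfig` collects every gate the screen applies; all comparisons
downstream are strict (>, <) against these values. Defaults are the
published screen's settings: FDR < 0.05 with |log2FC| > 1 for differential
expression, Spearman < -0.7 for miRNA-target pairs, Spearman > 0.9 for
lncRNA-mRNA pairs, raw hypergeometric p < 0.05 for ceRNA pairs, TPM > 4.5
for "highly expressed" miRNAs, and p < 0.05 for over-representation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .simulate import SimulationParams


@dataclass
class ThresholdConfig:
    fdr_max: float = 0.05
    abs_log2fc_min: float = 1.0
    scc_mirna_target_max: float = -0.7
    scc_lnc_mrna_min: float = 0.9
    cerna_p_max: float = 0.05
    tpm_high: float = 4.5
    enrichment_p_max: float = 0.05

    def validate(self) -> None:
        for name in ("scc_mirna_target_max", "scc_lnc_mrna_min"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValidationError(f"thresholds.{name}: {v} outside [-1, 1]")
        for name in ("fdr_max", "cerna_p_max", "enrichment_p_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"thresholds.{name}: {v} outside (0, 1]")
        if self.abs_log2fc_min < 0:
            raise ValidationError(f"thresholds.abs_log2fc_min: {self.abs_log2fc_min} < 0")


@dataclass
class PipelineConfig:
    """Full run description: either simulation params or input paths."""

    out_dir: Path
    simulation: SimulationParams | None = None
    inputs: dict[str, Path] | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    flagged_mirnas: list[str] = field(default_factory=list)
    gene_sets: Path | None = None
    universe: str = "all"  # miRNA universe for the hypergeometric test
    seed: int = 0
    log_level: str = "INFO"

    _INPUT_KEYS = (
        "lncrna_counts",
        "mirna_counts",
        "mrna_counts",
        "groups",
        "annotations",
        "interactions",
    )

    def validate(self) -> None:
        if self.simulation is None and self.inputs is None:
            raise ValidationError("config: one of 'simulation' or 'inputs' is required")
        if self.simulation is not None and self.inputs is not None:
            raise ValidationError("config: 'simulation' and 'inputs' are mutually exclusive")
        if self.inputs is not None:
            missing = [k for k in self._INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValidationError(f"inputs: missing keys {missing}")
        if self.universe not in ("all", "demis"):
            raise ValidationError(f"universe: {self.universe!r} not in ('all', 'demis')")
        self.thresholds.validate()
        if self.simulation is not None:
            self.simulation.validate()


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ValidationError(f"{section}: unknown key(s) {unknown}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config, fill defaults and check invariants."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    top_allowed = {
        "out_dir",
        "simulation",
        "inputs",
        "thresholds",
        "flagged_mirnas",
        "gene_sets",
        "universe",
        "seed",
        "log_level",
    }
    _check_keys(str(path), raw, top_allowed)
    if "out_dir" not in raw:
        raise ValidationError(f"{path}: 'out_dir' is required")

    thresholds = ThresholdConfig()
    if "thresholds" in raw:
        allowed = {f.name for f in dataclasses.fields(ThresholdConfig)}
        _check_keys("thresholds", raw["thresholds"], allowed)
        thresholds = ThresholdConfig(**raw["thresholds"])

    simulation = None
    if "simulation" in raw:
        allowed = {f.name for f in dataclasses.fields(SimulationParams)}
        _check_keys("simulation", raw["simulation"], allowed)
        sim_raw = dict(raw["simulation"])
        for key in ("gene_length_range", "library_size_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        simulation = SimulationParams(**sim_raw)
        if "seed" in raw and "seed" not in raw.get("simulation", {}):
            simulation.seed = int(raw["seed"])

    inputs = None
    if "inputs" in raw:
        _check_keys("inputs", raw["inputs"], set(PipelineConfig._INPUT_KEYS))
        inputs = {k: Path(v) for k, v in raw["inputs"].items()}

    config = PipelineConfig(
        out_dir=Path(raw["out_dir"]),
        simulation=simulation,
        inputs=inputs,
        thresholds=thresholds,
        flagged_mirnas=list(raw.get("flagged_mirnas", [])),
        gene_sets=Path(raw["gene_sets"]) if raw.get("gene_sets") else None,
        universe=raw.get("universe", "all"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    config.validate()
    return config
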