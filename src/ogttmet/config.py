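"""Validated configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

#: Fuzzy-cluster archetype labels for the four canonical oGTT trajectory shapes.
ARCHETYPE_LABELS = ("decline", "rise_plateau", "v_shape", "rise_fall")


class SimConfig(BaseModel):
    """Synthetic-cohort parameters.

    Defaults mirror the study design this package analyzes: 20 subjects per
    snack arm sampled at 0/15/30/60/120 min of a 2-h oral glucose tolerance
    test, ~200 annotated metabolites, four temporal archetypes, a planted
    standardized group effect of 1.5 on affected metabolites, log10-scale
    measurement noise of 0.2, and group-specific Matsuda-index correlations
    of 0.45 (almond) vs 0.0 (cracker) for a designated metabolite.
    """

    model_config = ConfigDict(frozen=True)

    n_per_group: int = 20
    n_metabolites: int = 200
    timepoints: tuple[float, ...] = (0, 15, 30, 60, 120)
    archetype_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # planted group effect (log10-AUC scale, standardized)
    n_affected: int = 20
    planted_g: float = 1.5

    # intensity model, all on log10 scale
    archetype_amplitude: float = 0.15
    base_log_mean: float = 4.5
    base_log_sd: float = 0.5
    subject_sd: float = 0.1
    noise_sd: float = 0.2
    missing_rate: float = 0.02

    # QC replicates and blanks
    qc_replicates: int = 8
    qc_rsd_range: tuple[float, float] = (0.05, 0.20)
    qc_rsd_high: float = 0.8
    n_high_rsd: int = 3
    n_blanks: int = 6
    n_blank_artifacts: int = 3
    blank_level: float = 0.01
    blank_artifact_scale: float = 1.5

    # chemical classes
    n_classes: int = 10
    enriched_class_size: int = 10
    biphasic_class_size: int = 0

    # clinical index correlations
    mi_corr_almond: float = 0.45
    mi_corr_cracker: float = 0.0

    seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "SimConfig":
        if self.n_per_group < 2:
            raise ValueError("invariant violated: n_per_group must be >= 2")
        if self.n_affected > self.n_metabolites:
            raise ValueError("invariant violated: n_affected <= n_metabolites")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValueError("invariant violated: archetype_weights must sum to 1")
        if any(w < 0 for w in self.archetype_weights):
            raise ValueError("invariant violated: archetype_weights must be non-negative")
        tp = self.timepoints
        if len(tp) < 3 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(
                "invariant violated: timepoints must be strictly increasing and start at 0"
            )
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("invariant violated: 0 <= missing_rate < 0.5")
        if self.enriched_class_size and self.n_affected < self.enriched_class_size:
            raise ValueError(
                "invariant violated: n_affected must cover enriched_class_size"
            )
        n_special = (
            self.n_high_rsd + self.n_blank_artifacts + self.biphasic_class_size
        )
        if self.n_affected + n_special > self.n_metabolites:
            raise ValueError(
                "invariant violated: affected + artifact + biphasic metabolites "
                "exceed n_metabolites"
            )
        if not (0 < self.qc_rsd_range[0] <= self.qc_rsd_range[1]):
            raise ValueError("invariant violated: qc_rsd_range must be 0 < low <= high")
        if self.seed < 0:
            raise ValueError("invariant violated: seed must be non-negative")
        return self


class PipelineConfig(BaseModel):
    """End-to-end analysis settings; either a synthetic cohort or an input dir."""

    model_config = ConfigDict(frozen=True)

    sim: Optional[SimConfig] = None
    input_dir: Optional[str] = None
    out_dir: str = "ogttmet_out"

    qc_rsd_threshold: float = 0.5
    blank_alpha: float = 0.05
    fdr_level: float = 0.05
    alpha: float = 0.05
    vip_threshold: float = 0.8
    loading_k_sd: float = 1.5
    max_components: int = 3
    n_clusters: int = 4
    fuzzifier: Optional[float] = None  # None -> estimate from data
    enrichment_min_size: int = 3
    tanimoto_min: float = 0.7
    g_floor: float = 0.8
    network_exclude_classes: tuple[str, ...] = ()
    auc_on_log10: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim / input_dir must be set")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        for name in ("qc_rsd_threshold", "blank_alpha", "fdr_level", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.tanimoto_min <= 1:
            raise ValueError("tanimoto_min must be in [0, 1]")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path
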