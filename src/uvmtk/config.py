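"""Pipeline configuration.

All thresholds the analysis stages consume live in one flat structure so a
run is fully described by (inputs, config, seed).  Defaults follow the
published uveal-melanoma analysis conventions: arm-level changes must reach
|log2| >= 0.2 and half the shortest-arm width, FDR control at 0.05, k = 6
neighbors for transcriptomic classification, MHC binders below 500 nM, and
17-mer mutant peptide windows scanned as 9-mers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    min_abs_log2: float = 0.2       # amplitude threshold for a CN change
    min_width_fraction: float = 0.5  # of the shortest autosome arm
    q_threshold: float = 0.05        # BH FDR level
    raw_p_threshold: float = 0.05    # per-cohort raw p for driver retention
    freq_quantile: float = 0.75      # alteration-frequency quantile cutoff
    knn_k: int = 6                   # neighbors for Spearman k-NN
    affinity_cutoff_nM: float = 500.0
    peptide_window: int = 17         # mutant peptide window length (odd)
    epitope_length: int = 9          # scanned epitope length
    min_allele_support: int = 10     # alt reads for signature analysis
    min_expression: float = 0.0      # strict lower bound for neoantigen transcripts
    arm_cover_fraction: float = 0.0  # optional stricter arm-event coverage rule
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "min_abs_log2", "min_width_fraction", "q_threshold",
            "raw_p_threshold", "affinity_cutoff_nM",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.freq_quantile < 1:
            raise ValueError("freq_quantile must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.peptide_window < self.epitope_length or self.peptide_window % 2 == 0:
            raise ValueError("peptide_window must be odd and >= epitope_length")
        if self.min_allele_support < 0 or self.min_expression < 0:
            raise ValueError("support/expression thresholds must be non-negative")
        if not 0 <= self.arm_cover_fraction <= 1:
            raise ValueError("arm_cover_fraction must lie in [0, 1]")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
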