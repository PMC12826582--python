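"""Analysis configuration and logging.

All thresholds that gate the pipeline live in :class:`AnalysisConfig` so that a
single object documents the analysis choices: the anchoring concentration, the
benchmark-response multiplier, the confidence-ratio filter, significance levels
and the kappa-network parameters.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import tomllib
from pathlib import Path

log = logging.getLogger("phenoanchor")


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds and defaults for the concentration-response pipeline.

    Attributes
    ----------
    anchor_concentration_uM:
        Genes whose benchmark concentration (BMC) is at or below this value are
        called phenotype-associated. Default 1.33 µM, the lowest tested
        concentration eliciting the anchoring phenotype.
    bmr_sd_multiplier:
        Benchmark response for gene expression, in residual standard deviations
        from control-level expression (default 1.35).
    ci_ratio_max:
        Maximum allowed BMCu/BMCl ratio for a gene to count as having a
        concentration response (default 40).
    de_alpha:
        BH-adjusted p-value cutoff for the differential-expression screen.
    enrichment_alpha:
        BH-adjusted p-value cutoff for term enrichment.
    kappa_threshold:
        Minimum Cohen's kappa for an edge between enriched terms.
    overlap_threshold:
        Minimum shared-gene fraction for merging functional groups.
    extra_risk:
        Extra-risk level R for dichotomous endpoint BMCs (default 0.20, i.e.
        BMC20).
    bmr_use_control_sd:
        If True, the BMR is expressed in control-group SDs instead of the
        fitted residual SD.
    bootstrap_B:
        Bootstrap replicates for the gene-BMC confidence interval.
    seed:
        Base seed for any stochastic step (bootstrap resampling).
    """

    anchor_concentration_uM: float = 1.33
    bmr_sd_multiplier: float = 1.35
    ci_ratio_max: float = 40.0
    de_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    kappa_threshold: float = 0.35
    overlap_threshold: float = 0.5
    extra_risk: float = 0.20
    bmr_use_control_sd: bool = False
    bootstrap_B: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "anchor_concentration_uM",
            "bmr_sd_multiplier",
            "ci_ratio_max",
            "de_alpha",
            "enrichment_alpha",
            "kappa_threshold",
            "overlap_threshold",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 < self.extra_risk < 1.0:
            raise ValueError("extra_risk must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config from a TOML file; keyword overrides win over file keys."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def setup_logging(level: int = logging.INFO) -> None:
    """Configure stage-prefixed logging to stderr (idempotent)."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level)


def echo_config(cfg: AnalysisConfig) -> None:
    log.info("effective config: %s", dataclasses.asdict(cfg))
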