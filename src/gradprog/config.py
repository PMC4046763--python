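"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid configuration values."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic three-tissue cohort.

    The defaults emulate the study design the pipeline targets: 10
    unpaired normal liver references plus 45 patients contributing a
    paired pericancerous and cancer sample each, expression on the log2
    scale with array-like baselines, a block of genes shifted gradually
    (half effect in pericancerous tissue, full effect in cancer), gene
    sets enriched for those gradual genes, six noisy redundant target
    databases, and exponential survival whose hazard follows the first
    planted prognostic signature.

    Attributes
    ----------
    n_normal, n_pairs:
        Normal reference samples and pericancerous/cancer patient pairs.
    n_genes, n_mirnas:
        Size of the gene and miRNA universes.
    n_sets, set_size_range:
        Number of gene sets and the inclusive size range they are drawn
        from.
    frac_gradual_up, frac_gradual_down:
        Fractions of the gene universe planted as gradually up- or
        down-shifted.
    delta:
        Full log2 shift in cancer vs normal for a gradual gene; the
        pericancerous shift is ``delta / 2``.
    noise_sd:
        Residual SD on the log2 scale.
    beta_surv:
        Log-hazard ratio per unit (standardized) risk score of the first
        planted prognostic set.
    censor_frac:
        Target fraction of censored patients (independent uniform
        censoring, upper bound tuned to hit this on average).
    db_recall, db_fpr:
        Per-database probability of reporting a true edge / a spurious
        edge.
    n_enriched_sets, enriched_member_frac, n_prognostic_sets:
        How many sets are planted as enriched, the fraction of their
        members drawn from gradual genes, and how many of those drive
        survival.
    targets_per_mirna:
        Mean number of true gene targets per miRNA.
    baseline_mean, baseline_sd:
        Gene baseline log2 intensities, drawn N(baseline_mean,
        baseline_sd).
    median_survival_months:
        Baseline median survival (sets the exponential baseline hazard).
    seed:
        Master seed; one independent RNG stream per generation stage is
        spawned from it so adding a stage never perturbs earlier draws.
    """

    n_normal: int = 10
    n_pairs: int = 45
    n_genes: int = 2000
    n_mirnas: int = 150
    n_sets: int = 40
    set_size_range: tuple[int, int] = (10, 30)
    frac_gradual_up: float = 0.05
    frac_gradual_down: float = 0.05
    delta: float = 4.0
    noise_sd: float = 0.8
    beta_surv: float = 1.0
    censor_frac: float = 0.2
    db_recall: float = 0.7
    db_fpr: float = 0.01
    n_enriched_sets: int = 6
    enriched_member_frac: float = 0.8
    n_prognostic_sets: int = 1
    targets_per_mirna: int = 8
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    median_survival_months: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.set_size_range = tuple(self.set_size_range)  # type: ignore[assignment]
        if self.n_normal < 2:
            raise ConfigError("n_normal must be >= 2")
        if self.n_pairs < 3:
            raise ConfigError("n_pairs must be >= 3")
        for name in ("n_genes", "n_mirnas", "n_sets"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ConfigError("set_size_range must satisfy 2 <= lo <= hi")
        for name in ("frac_gradual_up", "frac_gradual_down", "censor_frac",
                     "db_recall", "db_fpr", "enriched_member_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_gradual_up + self.frac_gradual_down > 1.0:
            raise ConfigError("gradual fractions sum above 1")
        if self.delta <= 0:
            raise ConfigError("delta must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        import math
        if not math.isfinite(self.beta_surv):
            raise ConfigError("beta_surv must be finite")
        if not 0 <= self.n_enriched_sets <= self.n_sets:
            raise ConfigError("n_enriched_sets out of range")
        if not 0 <= self.n_prognostic_sets <= max(self.n_enriched_sets, 1):
            raise ConfigError("n_prognostic_sets out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["set_size_range"] = list(self.set_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Thresholds and bookkeeping for an end-to-end run.

    The analysis thresholds default to the discovery procedure's
    published operating point: DEG = |log2FC| > 2 and BH-adjusted
    p < 0.001; a gene set is enriched when both enrichment criteria have
    BH-adjusted p < 0.05; a consensus target edge needs at least 3 of 6
    database votes.
    """

    lfc_threshold: float = 2.0
    de_alpha: float = 0.001
    enrich_alpha: float = 0.05
    min_votes: int = 3
    n_perm: int = 1000
    gsea_weight: float = 1.0
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.de_alpha <= 0 or self.enrich_alpha <= 0:
            raise ConfigError("thresholds must be positive")
        if self.min_votes < 1:
            raise ConfigError("min_votes must be >= 1")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig.from_dict(self.synthetic)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
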