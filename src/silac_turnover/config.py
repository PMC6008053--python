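"""Configuration objects for simulation and for the analysis pipeline.

Every tolerance and threshold used by the pipeline is a field here with its
default, and can be overridden from a YAML file (flat keys matching the
dataclass field names, optionally grouped under ``simulation:`` and
``pipeline:`` sections).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

__all__ = ["SimulationConfig", "PipelineConfig", "load_config"]


@dataclass
class SimulationConfig:
    """Design and noise parameters of the synthetic dynamic-SILAC experiment.

    Defaults reproduce the experimental design being emulated: a light-to-
    heavy medium switch with a final 4:1 heavy:light amino-acid ratio
    (``p_heavy = 0.8``), sampling at 0, 1, 3 and 7 days, three biological
    replicates each measured in triplicate injections, and a right-skewed
    (log-normal) half-life distribution with median 5.4 days spanning
    <1 to >20 days.
    """

    timepoints: tuple[float, ...] = (0.0, 1.0, 3.0, 7.0)
    n_replicates: int = 3
    n_injections: int = 3
    #: probability that a single Arg/Lys in a nascent protein is heavy
    p_heavy: float = 0.8
    n_proteins: int = 2000
    halflife_median_days: float = 5.4
    halflife_log_sd: float = 0.55
    #: peptides per protein ~ geometric with this mean, minimum 1
    peptides_per_protein_mean: float = 6.0
    missed_cleavage_prob: float = 0.2
    #: multiplicative log-normal noise on the emitted H/L ratio
    ratio_noise_log_sd: float = 0.1
    #: per-measurement-event probability that a peptide goes undetected
    dropout_prob: float = 0.1
    #: peptide detectability drawn uniformly from this range
    detectability_range: tuple[float, float] = (0.8, 1.0)
    #: condition name -> multiplier on the reference rate constant
    condition_multipliers: dict[str, float] = field(
        default_factory=lambda: {"mixed": 1.0}
    )
    #: number of multi-protein complexes and the member-count range
    n_complexes: int = 0
    complex_size_range: tuple[int, int] = (5, 15)
    #: intra-class correlation of log rate constants within a complex
    complex_icc: float = 0.5
    #: expected nascent missed-cleavage detections per sample (scaled by
    #: the mean labelled fraction at that timepoint)
    label_events_per_sample: float = 5000.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if 0.0 not in self.timepoints:
            raise ConfigError("timepoints must include 0 (the pre-switch sample)")
        if not 0.0 < self.p_heavy <= 1.0:
            raise ConfigError(f"p_heavy must lie in (0, 1], got {self.p_heavy}")
        for name, value in [
            ("missed_cleavage_prob", self.missed_cleavage_prob),
            ("dropout_prob", self.dropout_prob),
            ("complex_icc", self.complex_icc),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        for name, value in [
            ("halflife_median_days", self.halflife_median_days),
            ("peptides_per_protein_mean", self.peptides_per_protein_mean),
        ]:
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.halflife_log_sd < 0:
            raise ConfigError("halflife_log_sd must be non-negative")
        if self.n_proteins < 1 or self.n_replicates < 1 or self.n_injections < 1:
            raise ConfigError("n_proteins, n_replicates, n_injections must be >= 1")
        return self


@dataclass
class PipelineConfig:
    """Thresholds and options of the half-life analysis pipeline."""

    #: "MC+1" corrects with one factor of P(H) per labelable residue;
    #: "MC" reproduces the printed per-missed-cleavage rule
    exponent_rule: str = "MC+1"
    #: pool label counts across samples when estimating purity
    pooled_purity: bool = False
    #: minimum mean %old at t0 for a peptide to be retained
    t0_min_old: float = 0.9
    #: Tukey fence multiplier on the interquartile range
    tukey_k: float = 1.5
    #: additive tolerance when checking for a continuous decay
    monotonic_tolerance: float = 0.05
    #: k-means clusters for fast-turnover censoring, with its seed
    k_clusters: int = 6
    cluster_seed: int = 0
    #: censor to "<1 day" when cluster-mean %old at this day <= threshold
    censor_day: float = 1.0
    censor_threshold: float = 0.5
    #: include the t0 points in the no-intercept decay fit
    include_t0_in_fit: bool = True
    #: significance threshold for group comparisons (before Bonferroni)
    alpha: float = 0.05
    #: Welch (unequal-variance) t-test by default; False restores Student
    welch: bool = True
    #: use replicate means instead of pooled peptide values in comparisons
    replicate_means: bool = False
    #: complex-cohesion thresholds: annotated members and measured half-lives
    min_members: int = 5
    min_measured: int = 3
    #: random size-matched groups drawn for the cohesion null
    n_rep: int = 1000
    #: draw random groups with replacement within a group
    sample_with_replacement: bool = False

    def validate(self) -> "PipelineConfig":
        if self.exponent_rule not in ("MC", "MC+1"):
            raise ConfigError(
                f"exponent_rule must be 'MC' or 'MC+1', got {self.exponent_rule!r}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tukey_k < 0 or self.monotonic_tolerance < 0:
            raise ConfigError("tukey_k and monotonic_tolerance must be >= 0")
        return self


def _apply(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs).validate()


def load_config(path=None) -> tuple[SimulationConfig, PipelineConfig]:
    """Load (SimulationConfig, PipelineConfig) from a YAML file.

    The file may use ``simulation:`` / ``pipeline:`` sections or a flat
    mapping; unknown keys raise :class:`ConfigError`. ``path=None`` returns
    the defaults.
    """
    if path is None:
        return SimulationConfig().validate(), PipelineConfig().validate()
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    if "simulation" in data or "pipeline" in data:
        sim = _apply(SimulationConfig, data.get("simulation", {}) or {})
        pipe = _apply(PipelineConfig, data.get("pipeline", {}) or {})
        return sim, pipe
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    sim = _apply(SimulationConfig, {k: v for k, v in data.items() if k in sim_fields})
    pipe = _apply(PipelineConfig, {k: v for k, v in data.items() if k in pipe_fields})
    leftover = set(data) - sim_fields - pipe_fields
    if leftover:
        raise ConfigError(f"unknown config keys: {sorted(leftover)}")
    return sim, pipe
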