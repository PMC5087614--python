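"""Simulation and pipeline run configuration.

The defaults describe the emulated study design: two 48-well STRT libraries'
worth of FACS-sorted hESC wells overexpressing PRD-like homeobox constructs
(LEUTX_n, LEUTX_R, OTX2, DPRX) against an mCherry fluorescent control, with
spike-in rows for depth normalization and planted differential-expression,
embryo-activation and promoter-motif ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ReplicateGroup:
    """One FACS sort: a construct, a GFP gate, a number of wells, cells per well."""

    construct: str
    gfp_status: str  # "positive" | "negative"
    n_replicates: int
    cells_per_well: int

    def __post_init__(self):
        if self.n_replicates <= 0:
            raise InvalidConfigError(
                f"replicate group {self.construct}/{self.gfp_status} has zero replicates"
            )
        if self.gfp_status not in ("positive", "negative"):
            raise InvalidConfigError(f"bad gfp_status {self.gfp_status!r}")


def default_replicate_design() -> list[ReplicateGroup]:
    """48-well library: GFP+ triplicate sorts of 75 cells for LEUTX_n/OTX2/DPRX
    (two transfection replicates each), quadruplicate 50-cell sorts for LEUTX_R,
    a triplicate mCherry fluorescent control, per-construct GFP- triplicates and
    untransfected GFP- filler wells (whole-library negatives n=23)."""
    groups = [
        ReplicateGroup("LEUTX_n", "positive", 6, 75),
        ReplicateGroup("LEUTX_R", "positive", 4, 50),
        ReplicateGroup("OTX2", "positive", 6, 75),
        ReplicateGroup("DPRX", "positive", 6, 75),
        ReplicateGroup("mCherry", "positive", 3, 75),
        ReplicateGroup("LEUTX_n", "negative", 3, 75),
        ReplicateGroup("LEUTX_R", "negative", 3, 50),
        ReplicateGroup("OTX2", "negative", 3, 75),
        ReplicateGroup("DPRX", "negative", 3, 75),
        ReplicateGroup("mCherry", "negative", 3, 75),
        ReplicateGroup("untransfected", "negative", 8, 75),
    ]
    assert sum(g.n_replicates for g in groups) == 48
    return groups


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment generator.

    Counts are gamma-Poisson (negative binomial) with a per-sample capture
    multiplier applied to endogenous and spike-in rows alike; spike-in expected
    counts are otherwise independent of the construct, which is what makes them
    usable as a depth estimate.
    """

    n_tfes: int = 2000
    n_spikes: int = 20
    library_size_mean: float = 100_000.0  # tags per sample
    samples_per_library: int = 48
    replicate_design: list[ReplicateGroup] = field(default_factory=default_replicate_design)
    capture_efficiency_cv: float = 0.3
    dispersion: float = 0.2  # NB overdispersion (var = mu + dispersion * mu^2)
    base_log_sd: float = 3.0  # log-normal sd of baseline TFE expression (heavy zero tail)
    spike_fraction: float = 0.05  # fraction of tags drawn by the spike ladder
    frac_up: float = 0.05
    frac_down: float = 0.01
    lfc_mean: float = 3.0  # log2 effect size of planted targets
    lfc_sd: float = 0.5
    lfc_min: float = 2.0  # planted |log2FC| floor
    planting_min_expression: float = 10.0  # baseline tags/sample floor for planted TFEs
    motif_rate_target: float = 0.5
    motif_rate_background: float = 0.05
    activation_overlap: float = 0.5
    activation_fold: float = 4.0  # minimum 8-cell / oocyte ratio of activated genes
    n_activated: int = 100
    effect_constructs: tuple = ("LEUTX_n", "LEUTX_R", "OTX2", "DPRX")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfes < 1 or self.n_spikes < 2:
            raise InvalidConfigError("need n_tfes >= 1 and n_spikes >= 2")
        if self.frac_up + self.frac_down > 1:
            raise InvalidConfigError("frac_up + frac_down must be <= 1")
        for name in ("frac_up", "frac_down", "motif_rate_target",
                     "motif_rate_background", "activation_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.library_size_mean <= 0 or self.dispersion < 0:
            raise InvalidConfigError("library_size_mean must be > 0, dispersion >= 0")
        if self.capture_efficiency_cv < 0:
            raise InvalidConfigError("capture_efficiency_cv must be >= 0")
        self.replicate_design = [
            g if isinstance(g, ReplicateGroup) else ReplicateGroup(*g)
            for g in self.replicate_design
        ]

    def n_samples(self) -> int:
        return sum(g.n_replicates for g in self.replicate_design)


@dataclass
class RunConfig:
    """End-to-end pipeline settings (thresholds, window sizes, stage sizes)."""

    sim: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = 0.1
    overlap_alpha: float = 0.05
    motif_p_threshold: float = 1e-4
    window_upstream: int = 2000
    window_downstream: int = 500
    n_resamplings: int = 20  # D
    n_permutations: int = 100  # B
    constructs: tuple = ("LEUTX_n", "DPRX")
    require_direction_concordance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_threshold", "overlap_alpha", "motif_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside (0, 1]")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["replicate_design"] = [
            list(asdict(g).values()) for g in self.sim.replicate_design
        ]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "replicate_design" in sim_raw:
            sim_raw["replicate_design"] = [
                ReplicateGroup(*g) for g in sim_raw["replicate_design"]
            ]
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
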