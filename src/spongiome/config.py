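"""Analysis and simulation configuration objects.

Every numeric threshold used by the pipeline lives in ``AnalysisConfig``
so a run is fully described by one serializable object plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from spongiome.data import ParameterError


@dataclass
class AnalysisConfig:
    """All numeric thresholds of the analysis pipeline.

    Defaults follow the study design: core membership above 70% prevalence,
    exclusivity above 90% within-group prevalence, 5000-read rarefaction
    depth and minimum library size, 200 m navigability threshold, sequence
    clustering at ASV/99/97/95/90% identity, taxa considered for
    correlation networks when present in more than 10 samples per sponge
    type, and module-membership cutoff 0.8.
    """

    core_fraction: float = 0.7
    exclusive_prevalence: float = 0.9
    rarefaction_depth: int = 5000
    min_reads: int = 5000
    depth_threshold_m: float = 200.0
    clustering_thresholds: tuple[float, ...] = (1.00, 0.99, 0.97, 0.95, 0.90)
    min_occurrence_per_type: int = 10
    kme_threshold: float = 0.8
    vif_threshold: float = 10.0
    n_permutations: int = 999
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("core_fraction", "exclusive_prevalence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        thr = tuple(self.clustering_thresholds)
        if list(thr) != sorted(thr, reverse=True):
            raise ParameterError("clustering_thresholds must be sorted descending")
        if any(not 0 < t <= 1 for t in thr):
            raise ParameterError("clustering thresholds must be in (0, 1]")
        self.clustering_thresholds = thr
        if self.n_permutations < 99:
            raise ParameterError("n_permutations must be >= 99")
        if self.rarefaction_depth < 1:
            raise ParameterError("rarefaction_depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["clustering_thresholds"] = list(d["clustering_thresholds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "clustering_thresholds" in d:
            d["clustering_thresholds"] = tuple(d["clustering_thresholds"])
        return cls(**d)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data generator.

    ``n_species_per_type`` maps sponge type to number of host species;
    ``richness_mean_by_type`` sets the expected per-sample ASV richness
    (HMA above LMA reproduces the carrying-capacity ordering).
    ``decay_rate`` is per-km compositional turnover; ``env_effect_size``
    is the log-scale slope per environmental covariate on designated
    responsive taxa. ``dispersion`` is the Dirichlet concentration
    (larger = less compositional noise).
    """

    seed: int = 0
    n_species_per_type: dict[str, int] = field(
        default_factory=lambda: {"HMA": 3, "LMA_demo": 3, "LMA_glass": 2}
    )
    samples_per_species: int | tuple[int, int] = 4
    n_reference_samples: dict[str, int] = field(
        default_factory=lambda: {"seawater": 8, "sediment": 4}
    )
    n_locations: int = 6
    n_background_asvs: int = 120
    n_specific_asvs_per_species: int = 5
    exclusive_prevalence: float = 1.0
    richness_mean_by_type: dict[str, float] = field(
        default_factory=lambda: {"HMA": 80.0, "LMA_demo": 40.0, "LMA_glass": 30.0}
    )
    decay_rate: float = 0.0
    env_effect_size: float = 0.0
    n_env_parameters: int = 24
    depth_distribution: tuple[float, float] = (9.2, 0.35)  # lognormal mu, sigma
    min_library_size: int = 0
    dispersion: float = 200.0
    genus_fanout: int = 2
    family_fanout: int = 2
    order_fanout: int = 2
    n_classes: int = 2

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ParameterError(f"dispersion must be > 0, got {self.dispersion}")
        if not 0 < self.exclusive_prevalence <= 1:
            raise ParameterError("exclusive_prevalence must be in (0, 1]")
        if self.decay_rate < 0:
            raise ParameterError("decay_rate must be >= 0")
        if self.decay_rate > 0 and self.n_locations < 2:
            raise ParameterError("decay_rate > 0 requires n_locations >= 2")
        if any(v < 1 for v in self.n_species_per_type.values()):
            raise ParameterError("species counts must be >= 1")
        if self.n_background_asvs < 1:
            raise ParameterError("n_background_asvs must be >= 1")
        spp = self.samples_per_species
        if isinstance(spp, (tuple, list)):
            lo, hi = spp
            if lo < 1 or hi < lo:
                raise ParameterError("invalid samples_per_species range")
            self.samples_per_species = (int(lo), int(hi))

    def sample_count_range(self) -> tuple[int, int]:
        spp = self.samples_per_species
        if isinstance(spp, tuple):
            return spp
        return (int(spp), int(spp))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["depth_distribution"] = list(d["depth_distribution"])
        if isinstance(d["samples_per_species"], tuple):
            d["samples_per_species"] = list(d["samples_per_species"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "depth_distribution" in d:
            d["depth_distribution"] = tuple(d["depth_distribution"])
        if isinstance(d.get("samples_per_species"), list):
            d["samples_per_species"] = tuple(d["samples_per_species"])
        return cls(**d)
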