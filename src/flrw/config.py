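"""Pipeline configuration: one dataclass tree, YAML round-trippable.

``PipelineConfig.reference()`` freezes the reference operating point used
throughout: beta = 150, alpha = 0.5, 7000 samples per region, seeding
range [125, 155].
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .random_walk import WalkConfig
from .texture_features import FeatureWindowSpec

__all__ = ["ClassifierConfig", "SeedConfig", "DenoiseConfig", "PipelineConfig"]


@dataclass(frozen=True)
class ClassifierConfig:
    T: int = 10
    rho: float = 0.8
    sigma0: float | None = None  # None: median pairwise distance
    svm_C: float = 1.0
    n_per_region: int = 7000
    edge_band: int = 3
    resample_size: int = 2000
    variance_fraction: float = 0.95
    n_components: int | None = None

    def __post_init__(self):
        if self.T < 1 or not 0 < self.rho <= 1 or self.svm_C <= 0:
            raise ConfigError("invalid classifier settings")
        if self.n_per_region < 1 or self.edge_band < 1 or self.resample_size < 2:
            raise ConfigError("invalid sampling settings")


@dataclass(frozen=True)
class SeedConfig:
    search_range: tuple = (125.0, 155.0)
    erosion_radius: int = 2
    offset_below: float = 39.0  # 3 x 13 HU below the peak
    offset_above: float = 26.0  # 2 x 13 HU above the peak

    def __post_init__(self):
        if self.search_range[0] >= self.search_range[1] or self.erosion_radius < 0:
            raise ConfigError("invalid seed settings")


@dataclass(frozen=True)
class DenoiseConfig:
    method: str = "median"
    radius: int = 1

    def __post_init__(self):
        if self.method not in ("none", "median", "gaussian") or self.radius < 0:
            raise ConfigError("invalid denoise settings")


@dataclass(frozen=True)
class PipelineConfig:
    feature: FeatureWindowSpec = field(default_factory=FeatureWindowSpec)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seeds: SeedConfig = field(default_factory=SeedConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    seed: int = 0

    @classmethod
    def reference(cls) -> "PipelineConfig":
        """The frozen reference profile (beta 150, alpha 0.5, 7000 x 3)."""
        return cls()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature"]["glcm_offsets"] = [list(o) for o in self.feature.glcm_offsets]
        d["seeds"]["search_range"] = list(self.seeds.search_range)
        return d

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        feat = dict(d.get("feature", {}))
        if "glcm_offsets" in feat:
            feat["glcm_offsets"] = tuple(tuple(o) for o in feat["glcm_offsets"])
        seeds = dict(d.get("seeds", {}))
        if "search_range" in seeds:
            seeds["search_range"] = tuple(seeds["search_range"])
        try:
            return cls(
                feature=FeatureWindowSpec(**feat),
                classifier=ClassifierConfig(**d.get("classifier", {})),
                seeds=SeedConfig(**seeds),
                walk=WalkConfig(**d.get("walk", {})),
                denoise=DenoiseConfig(**d.get("denoise", {})),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as exc:
            raise ConfigError(f"unknown configuration key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path!r} is not a mapping")
        return cls.from_dict(d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
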