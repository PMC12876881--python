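"""Pipeline configuration: one parameter group per stage, YAML round-trip.

Headline defaults are the workflow's canonical settings (PAM threshold
fraction 0.87, viability cut-off 0.5, 10 CV folds, soft-tissue refractive
index 1.38); everything else is a documented design default and can be
overridden from a YAML file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("ocpam")

__all__ = [
    "SegmentationParams",
    "TrackingParams",
    "GrowthThresholds",
    "ViabilityParams",
    "RadiomicsParams",
    "ClassifierParams",
    "FusionParams",
    "ReconParams",
    "PipelineConfig",
]


@dataclass
class SegmentationParams:
    low_percentile: float = 1.0
    # 99.9 keeps the bright organoid tail unsaturated even when organoids
    # occupy well under 1% of the voxels (early imaging days)
    high_percentile: float = 99.9
    denoise_size: int = 3  # median-filter window (voxels)
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.15
    min_volume_um3: float = 250.0
    split_marker_distance_um: float = 20.0

    def validate(self) -> None:
        if not 0 <= self.low_percentile < self.high_percentile <= 100:
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        if self.min_volume_um3 < 0:
            raise ValueError("min_volume_um3 must be >= 0")
        if self.denoise_size < 1:
            raise ValueError("denoise_size must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


@dataclass
class TrackingParams:
    w_spatial: float = 0.5
    w_volume: float = 0.3
    w_bbox: float = 0.2
    sigma_d_um: float = 30.0
    tau: float = 0.4
    merge_overlap_fraction: float = 0.5

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_spatial, self.w_volume, self.w_bbox)

    def validate(self) -> None:
        if abs(self.w_spatial + self.w_volume + self.w_bbox - 1.0) > 1e-9:
            raise ValueError("matching weights must sum to 1")
        if self.sigma_d_um <= 0:
            raise ValueError("sigma_d_um must be > 0")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must lie in [0, 1]")
        if not 0 < self.merge_overlap_fraction <= 1:
            raise ValueError("merge_overlap_fraction must lie in (0, 1]")


@dataclass
class GrowthThresholds:
    f_plateau: float = 1.25  # per-interval fold-change at/below which an interval is flat
    plateau_intervals: int = 2  # consecutive flat intervals required for a plateau
    f_regrow: float = 10.0  # cumulative post-plateau fold for DTP regrowth
    rapid_log10: float = 2.0  # final relative volume class boundaries (decades)
    medium_log10: float = 1.0

    def validate(self) -> None:
        if self.f_plateau <= 0 or self.f_regrow <= 0:
            raise ValueError("fold thresholds must be > 0")
        if self.plateau_intervals < 1:
            raise ValueError("plateau_intervals must be >= 1")
        if self.medium_log10 >= self.rapid_log10:
            raise ValueError("medium boundary must sit below rapid boundary")


@dataclass
class ViabilityParams:
    cutoff: float = 0.5  # HIGH iff score strictly above
    clahe_clip_limit: float = 0.005
    clahe_tile_fraction: float = 0.125  # tile size as fraction of image extent
    double_positive: str = "dead"  # pixels positive in both channels

    def validate(self) -> None:
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must lie in [0, 1]")
        if self.double_positive not in ("dead", "live"):
            raise ValueError("double_positive must be 'dead' or 'live'")


@dataclass
class RadiomicsParams:
    n_levels: int = 32  # equal-width grey levels over the ROI range
    distance: int = 1  # co-occurrence offset length (voxels)
    min_roi_voxels: int = 27
    mode: str = "3d"  # "3d" | "2d" (per-slice, averaged)

    def validate(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.mode not in ("3d", "2d"):
            raise ValueError("mode must be '3d' or '2d'")


@dataclass
class ClassifierParams:
    n_estimators: int = 300
    max_depth: int = 4
    learning_rate: float = 0.1
    n_folds: int = 10
    group_by_well: bool = False

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_estimators < 1 or self.max_depth < 1 or self.learning_rate <= 0:
            raise ValueError("invalid booster settings")


@dataclass
class FusionParams:
    threshold_fraction: float = 0.87
    scope: str = "per_aline"  # "per_aline" | "global"
    noise_sigma_mult: float = 5.0  # noise floor = mean + mult * SD of background
    residual_ceiling_um: float = 10.0

    def validate(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.scope not in ("per_aline", "global"):
            raise ValueError("scope must be 'per_aline' or 'global'")


@dataclass
class ReconParams:
    n_medium: float = 1.38  # soft-tissue refractive index
    db_floor: float = -40.0  # display floor for log compression (dB below peak)
    interp: str = "cubic"  # wavelength -> wavenumber resampling

    def validate(self) -> None:
        if self.n_medium <= 0:
            raise ValueError("n_medium must be > 0")
        if self.db_floor >= 0:
            raise ValueError("db_floor must be negative (dB below peak)")


@dataclass
class PipelineConfig:
    """All stage parameter groups, YAML-serialisable."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    growth: GrowthThresholds = field(default_factory=GrowthThresholds)
    viability: ViabilityParams = field(default_factory=ViabilityParams)
    radiomics: RadiomicsParams = field(default_factory=RadiomicsParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    recon: ReconParams = field(default_factory=ReconParams)

    _GROUPS = {
        "segmentation": SegmentationParams,
        "tracking": TrackingParams,
        "growth": GrowthThresholds,
        "viability": ViabilityParams,
        "radiomics": RadiomicsParams,
        "classifier": ClassifierParams,
        "fusion": FusionParams,
        "recon": ReconParams,
    }

    def validate(self) -> "PipelineConfig":
        for name in self._GROUPS:
            getattr(self, name).validate()
        return self

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name)) for name in self._GROUPS}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for name, group_cls in cls._GROUPS.items():
            section = d.get(name, {})
            known = {f.name for f in dataclasses.fields(group_cls)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            kwargs[name] = group_cls(**section)
        unknown_sections = set(d) - set(cls._GROUPS)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        return cls(**kwargs).validate()

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def log_resolved(self) -> None:
        """Log the fully-resolved configuration for reproducibility."""
        logger.info("resolved config: %s", self.to_dict())
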