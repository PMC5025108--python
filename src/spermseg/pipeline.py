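"""End-to-end per-frame pipeline: LoG -> PSO-tuned ICM -> head centroids."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from spermseg.features import (
    Region,
    centroids,
    filter_border,
    label_regions,
    regions_to_mask,
)
from spermseg.fitness import FitnessConfig
from spermseg.preprocess import LoGConfig, apply_log
from spermseg.pso import OptimizationResult, SwarmConfig, optimize

__all__ = ["FeatureConfig", "PipelineConfig", "SegmentationResult", "segment_frame"]


@dataclass(frozen=True)
class FeatureConfig:
    """Region post-processing knobs.

    min_area is opt-in (0 disables it): debris is normally rejected by the
    intensity-driven segmentation itself, not by size.
    """

    connectivity: int = 8
    border_margin: int = 1
    min_area: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for every stage, with documented defaults."""

    log: LoGConfig = field(default_factory=LoGConfig)
    pso: SwarmConfig = field(default_factory=SwarmConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a nested mapping, e.g. a parsed YAML file.

        Recognised sections: ``log``, ``icm``, ``pso``, ``fitness``,
        ``features``; unknown keys raise so typos never pass silently.
        The ``icm`` section may override ``e_init`` and ``n_max`` (the other
        network constants are produced by the optimizer, not configured).
        """
        raw = dict(raw)
        icm_section = dict(raw.pop("icm", {}))
        sections: dict[str, Any] = {}
        builders = {
            "log": LoGConfig,
            "pso": SwarmConfig,
            "fitness": FitnessConfig,
            "features": FeatureConfig,
        }
        for name, builder in builders.items():
            opts = dict(raw.pop(name, {}))
            if name == "pso":
                if "h_low" in opts or "h_high" in opts:
                    lo = opts.pop("h_low", SwarmConfig().h_range[0])
                    hi = opts.pop("h_high", SwarmConfig().h_range[1])
                    opts["h_range"] = (lo, hi)
                if "n_max" in icm_section:
                    opts.setdefault("n_max", icm_section.pop("n_max"))
            try:
                sections[name] = builder(**opts)
            except TypeError as exc:
                raise ValueError(f"bad option in section '{name}': {exc}") from exc
        icm_section.pop("e_init", None)  # accepted but fixed at 5 for now
        if icm_section:
            raise ValueError(f"unknown icm options: {sorted(icm_section)}")
        if raw:
            raise ValueError(f"unknown config sections: {sorted(raw)}")
        return cls(**sections)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, pso=replace(self.pso, seed=seed))


@dataclass
class SegmentationResult:
    """Everything one frame produces."""

    mask: np.ndarray  # border-filtered segmentation, {0,1}
    raw_mask: np.ndarray  # pulse image straight from the network
    centroids: list[tuple[float, float]]
    regions: list[Region]
    optimization: OptimizationResult
    stimulus: np.ndarray  # the LoG-filtered image fed to the network


def segment_frame(
    image: np.ndarray, config: PipelineConfig = PipelineConfig()
) -> SegmentationResult:
    """Detect sperm heads in one grayscale [0, 1] frame.

    Stages: LoG blob enhancement; per-frame swarm search for the network
    constants (f, g, h, n) minimising the feature-MI error; one final
    network run with the winning constants; connected-component labelling
    with border rejection and optional minimum-area filtering; centroid
    extraction.
    """
    image = np.asarray(image, dtype=float)
    stimulus = apply_log(image, config.log)
    result = optimize(image, stimulus, config.pso, config.fitness)
    regions = label_regions(result.best_mask, config.features.connectivity)
    regions = filter_border(regions, image.shape, config.features.border_margin)
    if config.features.min_area > 0:
        regions = [r for r in regions if r.area >= config.features.min_area]
    mask = regions_to_mask(regions, image.shape)
    return SegmentationResult(
        mask=mask,
        raw_mask=result.best_mask,
        centroids=centroids(regions),
        regions=regions,
        optimization=result,
        stimulus=stimulus,
    )
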