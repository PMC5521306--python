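"""Pipeline configuration: every tunable parameter with its default.

Defaults equal the study's stated values (10-Hz acquisition, 0.02-0.5 Hz
band, 1-Hz analysis rate, HRF landmarks 2/7/17 s, 18-mm seed relocation
limit, 9-mm ROI cubes, voxelwise p < 0.001 with cluster p < 0.05,
Bonferroni family alpha 0.05 over 10 comparisons).  Configs serialize
to/from YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "HRFConfig", "FilterConfig", "SeedConfig",
           "StatsConfig", "SimConfig"]


@dataclass
class HRFConfig:
    rate: float = 10.0
    duration_s: float = 32.0
    delay_s: float = 2.0
    peak_s: float = 7.0
    undershoot_s: float = 17.0
    undershoot_ratio: float = 0.2


@dataclass
class FilterConfig:
    low_hz: float = 0.02
    high_hz: float = 0.5
    target_rate_hz: float = 1.0


@dataclass
class SeedConfig:
    mask_radius_mm: float = 3.0      # seed definition: 6-mm-diameter sphere
    signal_radius_mm: float = 6.0    # signal extraction: 6-mm-radius sphere
    max_peak_dist_mm: float = 18.0
    peak_min_z: float = 3.0902       # one-sided p < 0.001


@dataclass
class StatsConfig:
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    n_permutations: int = 200
    overlap_z: float = 1.6
    alpha_family: float = 0.05
    two_tailed: bool = True
    use_thresholded_matrices: bool = True


@dataclass
class SimConfig:
    n_subjects: int = 4
    n_runs: int = 4
    voxel_size_mm: float = 3.0
    acquisition_rate_hz: float = 10.0
    isi_range_s: tuple = (2.0, 10.0)
    stim_duration_s: float = 2.0
    superficial_amp: float = 3.0
    pink_amp: float = 2.0
    white_amp: float = 1.0
    neural_noise_sd: float = 2.0
    neural_noise_tau_s: float = 1.0


@dataclass
class PipelineConfig:
    hrf: HRFConfig = field(default_factory=HRFConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    seeds: SeedConfig = field(default_factory=SeedConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    deconv_lambda: object = "auto"
    interaction_levels: tuple = ("hemodynamic", "neural")
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["sim"]["isi_range_s"] = list(d["sim"]["isi_range_s"])
        d["interaction_levels"] = list(d["interaction_levels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        sub = {"hrf": HRFConfig, "filter": FilterConfig, "seeds": SeedConfig,
               "stats": StatsConfig, "sim": SimConfig}
        for key, klass in sub.items():
            if key in d:
                section = dict(d.pop(key))
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(section) - known
                if unknown:
                    raise ValueError(f"unknown config keys in {key}: {sorted(unknown)}")
                if key == "sim" and "isi_range_s" in section:
                    section["isi_range_s"] = tuple(section["isi_range_s"])
                kwargs[key] = klass(**section)
        top_known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - top_known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "interaction_levels" in d:
            d["interaction_levels"] = tuple(d["interaction_levels"])
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
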