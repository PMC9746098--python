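"""Pipeline configuration with a lossless YAML round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .core import SizeClassConfig


@dataclass
class PipelineConfig:
    # size classes: (lower_bp, upper_bp, merge_window_bp), upper-inclusive
    size_classes: list = field(
        default_factory=lambda: [
            [50, 100, 50],
            [100, 500, 100],
            [500, 1000, 500],
            [1000, 30000, 1000],
        ]
    )
    large_window_bp: int = 10_000  # SVs > 30 kb and translocations
    somatic_window_equals_class: bool = True

    # consensus selection
    min_replicates: int = 2
    min_platforms: int = 2
    min_tools: int = 2
    exclude_tenx_del_below_bp: int = 20_000

    # Hi-C detection
    hic_bin_width_bp: int = 50_000
    hic_mapq_min: int = 20
    hic_quadrant_range_bins: int = 10
    hic_z_min: float = 1.0
    hic_local_max_range_bins: int = 3
    hic_min_score: float = 6.0
    hic_min_quadrant_mass: int = 50
    hic_refine_half_window_bp: int = 2_000_000
    hic_refine_decay_bp: float | None = None  # default: 5 x bin width
    hic_theta: float = 2.5

    # orthogonal matching
    match_min_size_bp: int = 500
    match_size_similarity_min: float = 0.5
    match_max_distance_bp: int = 10_000
    match_tra_max_distance_bp: int = 50_000

    seed: int = 0

    def size_class_config(self) -> SizeClassConfig:
        return SizeClassConfig(
            classes=tuple(tuple(c) for c in self.size_classes),
            large_window=self.large_window_bp,
        )

    def validate(self):
        for name in (
            "min_replicates", "min_platforms", "min_tools", "hic_bin_width_bp",
            "hic_quadrant_range_bins", "hic_local_max_range_bins",
            "match_max_distance_bp", "match_tra_max_distance_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.size_class_config()
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(CONFIG_HEADER)
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()


CONFIG_HEADER = """\
# multisv pipeline configuration.
#
# size_classes / large_window_bp: merge windows per SV size class
#   (50-100 bp -> 50 bp window, ..., >30 kb and translocations -> 10 kb).
# min_replicates: replicate call sets required for the initial call set.
# min_platforms / min_tools: agreement required for the high-confidence set.
# exclude_tenx_del_below_bp: drop linked-read deletions below this size.
# hic_*: contact-matrix junction detection (bin width, MAPQ floor, quadrant
#   range R, z threshold, local-maximum range, deterministic filter, and
#   exponential-kernel refinement parameters).
# match_*: orthogonal-validation matching criteria (size floor, >50%
#   reciprocal size similarity, 10 kb distance; 50 kb for translocations).
"""
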