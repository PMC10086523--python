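"""Pipeline configuration with the defaults used throughout the analysis.

Defaults mirror the published analysis settings: compartments at 100 kb,
TADs at 40 kb with boundary FDR 0.01, HiCCUPS-style loop calling at
5/10/25 kb with per-resolution FDR 0.1, peak widths 4/2/1, windows 7/5/3,
merge distances 20/20/50 kb and enrichment thresholds (0.02, 1.5, 1.75, 2),
CCAN cutoff 0.1, aggregation k = 40 with <=10% mean shared cells, and
peak-to-gene filters (distance <= 500 kb, correlation > 0.45, FDR < 1e-4,
5 k-means clusters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CompartmentConfig",
    "TadCallConfig",
    "DoDConfig",
    "LoopCallConfig",
    "CCANConfig",
    "AggregateConfig",
    "LinkageConfig",
    "PipelineConfig",
]


@dataclass
class CompartmentConfig:
    resolution: int = 100_000
    n_quantiles: int = 50          # saddle quantiles
    corner_fraction: float = 0.2   # extreme quantile share defining saddle corners


@dataclass
class TadCallConfig:
    resolution: int = 40_000
    window_sizes: tuple[int, ...] = (4, 6, 8, 10)  # bins
    boundary_fdr: float = 0.01
    delta: float = 0.01            # min score drop vs flanking maxima
    match_tol_bins: int = 1
    min_domain_bins: int = 3
    connectivity_denominator: str = "sum"  # "sum" or "mean" of flank counts


@dataclass
class DoDConfig:
    k: int = 3
    ww: int = 5     # accepted for interface parity; not used by the statistic
    pw: int = 2     # accepted; unused
    top: float = 0.7
    ratio: float = 0.05  # accepted; unused
    gap: float = 0.2     # accepted; unused


@dataclass
class LoopCallConfig:
    resolutions: tuple[int, ...] = (5_000, 10_000, 25_000)
    fdr: tuple[float, ...] = (0.1, 0.1, 0.1)
    peak_widths: tuple[int, ...] = (4, 2, 1)        # bins
    windows: tuple[int, ...] = (7, 5, 3)            # bins
    merge_distances: tuple[int, ...] = (20_000, 20_000, 50_000)  # bp
    min_diagonal_distances: tuple[int, ...] = (20_000, 20_000, 50_000)  # bp
    # (max cluster q, obs/exp_h&v, obs/exp_donut, obs/exp_lowerleft)
    enrichment_thresholds: tuple[float, ...] = (0.02, 1.5, 1.75, 2.0)

    def __post_init__(self) -> None:
        lens = {
            len(self.resolutions),
            len(self.fdr),
            len(self.peak_widths),
            len(self.windows),
            len(self.merge_distances),
            len(self.min_diagonal_distances),
        }
        if len(lens) != 1:
            raise ValueError("per-resolution lists must all share one length")


@dataclass
class CCANConfig:
    cutoff: float = 0.1
    min_size: int = 3
    louvain_resolution: float = 1.0


@dataclass
class AggregateConfig:
    k: int = 40                 # cells per aggregate
    n_aggregates: int = 50      # target aggregates per condition
    max_mean_overlap: float = 0.10  # mean pairwise shared-cell fraction
    required_median_overlap: int = 0
    n_components: int = 10      # PCA dims for neighbor search


@dataclass
class LinkageConfig:
    max_distance: int = 500_000
    correlation_threshold: float = 0.45
    fdr_threshold: float = 1e-4
    n_clusters: int = 5


@dataclass
class PipelineConfig:
    compartments: CompartmentConfig = field(default_factory=CompartmentConfig)
    tads: TadCallConfig = field(default_factory=TadCallConfig)
    dod: DoDConfig = field(default_factory=DoDConfig)
    loops: LoopCallConfig = field(default_factory=LoopCallConfig)
    ccan: CCANConfig = field(default_factory=CCANConfig)
    aggregates: AggregateConfig = field(default_factory=AggregateConfig)
    linkages: LinkageConfig = field(default_factory=LinkageConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            sub = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name != "seed":
                sub_cls = {
                    "compartments": CompartmentConfig,
                    "tads": TadCallConfig,
                    "dod": DoDConfig,
                    "loops": LoopCallConfig,
                    "ccan": CCANConfig,
                    "aggregates": AggregateConfig,
                    "linkages": LinkageConfig,
                }[f.name]
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
                }
                kwargs[f.name] = sub_cls(**sub)
            else:
                kwargs[f.name] = sub
        return cls(**kwargs)
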