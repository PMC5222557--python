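"""Run configuration: every tunable the pipeline stages expose, with the
package defaults, YAML round-trip, and validation.

The config is serialized verbatim into a JSON sidecar next to every output
so each artifact records the exact parameters (and seed) that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    # track construction
    bin_size: int = 100              # bp, stranded coverage bins
    smooth_window: int = 1500        # bp, sliding-median window
    # origin calling
    oem_window: int = 12_000         # bp, one-sided transition-metric window
    threshold: float = 0.1           # transition-metric call threshold
    min_separation: int = 12_000     # bp, merge distance between maxima
    efficiency_radius: int = 20_000  # bp, efficiency search radius
    tz_radius: int = 25_000          # bp, transition-zone search radius
    # chromatin association
    origin_halfwidth: int = 2500     # bp, origin 5 kb block half-width
    min_fold: float = 5.0            # ChIP fold-enrichment filter (strict >)
    assoc_flank: int = 2500          # bp, signal averaging around midpoints
    # gene / transcriptome context
    flank: int = 25_000              # bp, profile half-width around origins
    gene_bin: int = 2500             # bp, distance-bin width
    top_n: int = 1000                # origins retained for coupling heatmap
    k_clusters: int = 6              # maternal/zygotic k-means clusters
    # simulation
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_origins: int = 125
    n_cells: int = 2000
    fragments_per_cell: int = 500
    fork_speed: float = 2.5          # kb/min
    efficiency_family: str = "beta"
    efficiency_params: tuple = (2.0, 2.0)
    seed: int = 0

    def validate(self) -> "RunConfig":
        positive = [
            "bin_size", "smooth_window", "oem_window", "min_separation",
            "efficiency_radius", "tz_radius", "origin_halfwidth", "flank",
            "gene_bin", "top_n", "k_clusters", "n_chrom", "chrom_length",
            "n_origins", "n_cells", "fragments_per_cell",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        for name in ["smooth_window", "oem_window", "efficiency_radius",
                     "tz_radius", "flank"]:
            if getattr(self, name) < self.bin_size:
                raise ValueError(f"{name} must be >= bin_size")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["efficiency_params"] = list(d["efficiency_params"])
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "efficiency_params" in d:
            d = {**d, "efficiency_params": tuple(d["efficiency_params"])}
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
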