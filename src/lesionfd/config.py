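"""Run configuration: one place for every threshold, losslessly serializable."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import GridSpec
from .synthetic import CohortTruth


@dataclass(frozen=True)
class Thresholds:
    """Every fixed analysis constant, each appearing exactly once."""

    tbr_cutoff: float = 1.6
    bin_edges: tuple[float, ...] = (1.6, 2.6, 3.6, 4.6, float("inf"))
    min_bin_volume_mL: float = 0.25
    edema_min_volume_mL: float = 10.0
    gliosis_max_volume_mL: float = 0.1
    gliosis_min_months: float = 6.0
    exceedance_relative_fd: float = 1.0
    outlier_relative_fd: float = 1.5


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_patients: int = 30
    n_controls: int = 30
    grid: GridSpec = field(default_factory=lambda: GridSpec(shape=(48, 48, 48)))
    truth: CohortTruth = field(default_factory=CohortTruth)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, truth=dataclasses.replace(self.truth, seed=seed)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"]["bin_edges"] = [
            "inf" if e == float("inf") else e for e in d["thresholds"]["bin_edges"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            g = dict(d["grid"])
            for k in ("shape", "voxel_size_mm", "origin_mm"):
                if k in g:
                    g[k] = tuple(g[k])
            d["grid"] = GridSpec(**g)
        if "truth" in d and isinstance(d["truth"], dict):
            d["truth"] = CohortTruth(**d["truth"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            t = dict(d["thresholds"])
            if "bin_edges" in t:
                t["bin_edges"] = tuple(float("inf") if e == "inf" else float(e) for e in t["bin_edges"])
            d["thresholds"] = Thresholds(**t)
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)
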