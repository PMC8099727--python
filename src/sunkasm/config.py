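"""Run configuration: every module's tunables in one serializable block.

Defaults are the toolkit's operating point: k = 20 SUNK anchors, k = 21
quality-value k-mers, k = 50 ChIP k-mers, pair thresholds 50 shared / 10
partners / 3 valid / ±1 % of read length, 5-kb identity windows, 10-kb
divergence windows, 10-unit entropy windows, Ne = 10,000 and a 20–29-year
generation time. One global seed fans out to per-module seeds by stable
hashing of the module name, so any stage can be re-run reproducibly in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 0
    # SUNK library
    sunk_k: int = 20
    sunk_coverage_band: tuple[float, float] = (0.5, 1.5)
    sunk_validation_min_count: int = 1
    # pairing / tiling
    min_shared_sunks: int = 50
    min_support_partners: int = 10
    min_valid_sunks: int = 3
    distance_tolerance_fraction: float = 0.01
    # identity heat map
    heatmap_window: int = 5000
    heatmap_identity_floor: float = 70.0
    # HOR analysis
    hor_start_monomer: str = "A"
    entropy_window_units: int = 10
    entropy_slide_units: int = 1
    # quality values
    qv_k: int = 21
    # ChIP k-mer mapping
    chip_k: int = 50
    chip_bin_size: int = 1000
    # evolution
    divergence_window: int = 10_000
    min_orthologous: int = 5000
    Ne: int = 10_000
    generation_years: tuple[float, float] = (20.0, 29.0)
    mc_draws: int = 10_000

    def module_seed(self, module: str) -> int:
        """Stable per-module seed derived from the global seed."""
        digest = hashlib.sha256(f"{module}".encode()).digest()
        return (self.seed ^ int.from_bytes(digest[:4], "big")) % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sunk_coverage_band"] = list(d["sunk_coverage_band"])
        d["generation_years"] = list(d["generation_years"])
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sunk_coverage_band" in d:
            d["sunk_coverage_band"] = tuple(d["sunk_coverage_band"])
        if "generation_years" in d:
            d["generation_years"] = tuple(d["generation_years"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
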