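"""Pipeline configuration: one YAML file, one seed, explicit thresholds.

Every analysis threshold lives here with its standard default (DMC
difference 0.10/0.10/0.07 for CG/CHG/CHH and posterior probability
0.9999; hyper/hypo direction cutoffs 0.25/0.25/0.10; DEG filter
CPM > 10, padj < 0.05, |log2FC| > 1; promoter length 2000 bp; smoothing
window 500 bp; DMR minimum length 50 bp / 3 sites / merge gap 100 bp).
Configs round-trip through YAML unchanged, and a config hash is logged
with every run so assumption drift stays visible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ThresholdConfig", "SolverConfig", "PipelineConfig"]


@dataclass
class ThresholdConfig:
    dmc_diff_cg: float = 0.10
    dmc_diff_chg: float = 0.10
    dmc_diff_chh: float = 0.07
    dmc_p_post: float = 0.9999
    direction_cutoff_cg: float = 0.25
    direction_cutoff_chg: float = 0.25
    direction_cutoff_chh: float = 0.10
    deg_min_cpm: float = 10.0
    deg_max_padj: float = 0.05
    deg_min_abs_l2fc: float = 1.0
    promoter_length: int = 2000
    smoothing_window: int = 500
    dmr_min_len: int = 50
    dmr_min_sites: int = 3
    dmr_merge_gap: int = 100
    dmr_pct_sig: float = 0.5


@dataclass
class SolverConfig:
    feas_tol: float = 1e-9
    relative_tolerance: float = 0.0  # 0 = strict equality constraints


@dataclass
class PipelineConfig:
    seed: int = 0
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    paths: dict[str, str] = field(default_factory=dict)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = (
            Path(source).read_text()
            if (isinstance(source, Path) or Path(str(source)).exists())
            else str(source)
        )
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        missing = []
        thr = data.get("thresholds")
        if thr is None:
            missing.append("thresholds")
            thr = {}
        for key in (f.name for f in dataclasses.fields(ThresholdConfig)):
            if thr and key not in thr:
                missing.append(f"thresholds.{key}")
        if missing:
            raise ValueError(f"config missing key(s): {missing}")
        return cls(
            seed=int(data.get("seed", 0)),
            thresholds=ThresholdConfig(**thr),
            solver=SolverConfig(**data.get("solver", {})),
            paths=dict(data.get("paths", {})),
        )

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    # -- adapters into the analysis modules ------------------------------
    def dmc_thresholds(self):
        from .methylome.calls import DmcThresholds

        t = self.thresholds
        return DmcThresholds(t.dmc_diff_cg, t.dmc_diff_chg, t.dmc_diff_chh, t.dmc_p_post)

    def dmr_parameters(self):
        from .methylome.calls import DmrParameters

        t = self.thresholds
        return DmrParameters(t.dmr_min_len, t.dmr_min_sites, t.dmr_merge_gap, t.dmr_pct_sig)

    def deg_filter(self):
        from .integrate import DegFilter

        t = self.thresholds
        return DegFilter(t.deg_min_cpm, t.deg_max_padj, t.deg_min_abs_l2fc)
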