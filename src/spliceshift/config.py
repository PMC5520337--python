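"""Pipeline configuration: a flat YAML file mapping to one dataclass."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .cluster import LINKAGES
from .synthetic import DEFAULT_CELL_LINES, NoiseParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full screen run needs, simulator settings included.

    When ``catalog_path`` / ``peaks_path`` are set the pipeline consumes
    those tables instead of simulating; otherwise a synthetic screen of
    ``n_ases`` events across ``cell_lines`` is generated from ``seed``.
    """

    outdir: str = "spliceshift_out"
    seed: int = 1
    # simulator
    n_ases: int = 96
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES
    prop_null: float = 0.6
    effect_mean_abs: float = 20.0
    effect_sd: float = 6.0
    discordant_rate: float = 0.05
    response_rate: float = 0.5
    baseline_sd: float = 50.0
    size_jitter_sd: float = 0.02
    amount_cv: float = 0.05
    use_traces: bool = False
    # analysis
    threshold: float = 8.0
    rel_tol: float = 0.10
    min_total: float = 0.05
    linkage: str = "average"
    lenient: bool = False
    # optional external inputs
    catalog_path: Optional[str] = None
    peaks_path: Optional[str] = None
    gmt_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.cell_lines = tuple(self.cell_lines)
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.rel_tol < 0.5:
            raise ValueError("rel_tol must be in (0, 0.5)")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.n_ases <= 0:
            raise ValueError("n_ases must be >= 1")
        for p in (self.catalog_path, self.peaks_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @property
    def noise(self) -> NoiseParams:
        return NoiseParams(
            baseline_sd=self.baseline_sd,
            size_jitter_sd=self.size_jitter_sd,
            amount_cv=self.amount_cv,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["cell_lines"] = list(self.cell_lines)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
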