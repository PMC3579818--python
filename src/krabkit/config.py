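"""Pipeline configuration: the analysis constants in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline with their study defaults.

    Units: base pairs for genomic distances/windows, nCounter counts for the
    expression threshold, percent for the homology threshold.
    """

    max_gap: int = 200_000  # bp between neighbouring genes of one cluster
    homology_threshold: float = 70.0  # % identity over alignment columns
    expression_threshold: float = 99.0  # counts; expressed iff mean > θ
    genorm_m_cutoff: float = 0.5  # reference genes need M below this
    alpha: float = 0.05  # adjusted-p cutoff (0.01 available as preset)
    min_fold: float = 2.0  # between-group fold-change filter
    promoter_up: int = 3_500  # bp upstream of the TSS
    promoter_down: int = 500  # bp downstream of the TSS
    flank: int = 3_500  # bp around the gene body (extended window)
    n_bins: int = 8  # meta-gene bins over the extended window
    erv_min_len: int = 500  # bp; shorter ERVs are dropped
    background_floor: float = 0.1  # counts after background subtraction
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_gap", "homology_threshold", "expression_threshold",
            "genorm_m_cutoff", "min_fold", "promoter_up", "promoter_down",
            "flank", "n_bins", "erv_min_len", "background_floor",
        ):
            if getattr(self, name) <= 0 and name != "expression_threshold":
                raise ValueError(f"{name} must be positive")
        if self.expression_threshold < 0:
            raise ValueError("expression_threshold must be ≥ 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a flat JSON config; keyword overrides (e.g. CLI flags) win."""
    values: dict = {}
    if path is not None:
        values.update(json.loads(Path(path).read_text()))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)
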