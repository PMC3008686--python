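"""Run configuration: the knobs of a full enrichment run, with YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of an enrichment run.

    Defaults are the study conditions the package is built around: 500 bp
    promoters, 100 random sets for the empirical null, FDR 5%, pseudocount
    0.25 per matrix cell, clustering overlap 0.2, double-stranded scanning.
    """

    promoter_len: int = 500
    n_random_sets: int = 100
    fdr: float = 0.05
    pseudocount: float = 0.25
    cluster_overlap_x: float = 0.2
    strands: str = "both"
    seed: int = 0
    p_value_mode: str = "normal_cdf"
    score_mode: str = "log_ratio"
    em_tol: float = 1e-6
    em_max_iter: int = 100
    em_init_entry: float = 0.01

    def __post_init__(self) -> None:
        if self.strands not in ("both", "forward"):
            raise ValueError(f"strands must be 'both' or 'forward', got {self.strands!r}")
        if self.p_value_mode not in ("normal_cdf", "rank"):
            raise ValueError(f"unknown p_value_mode {self.p_value_mode!r}")
        if self.score_mode not in ("log_ratio", "raw_ratio"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
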