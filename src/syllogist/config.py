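"""Run configuration: every tunable of a scoring run, serializable with a digest.

Defaults follow the published procedure where it states them (80-gene
signatures, 1000 random lists) and the package's documented choices where
it does not (expression threshold, odds-ratio correction, universe).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a scoring run.

    signature_size: marker genes per lineage (m).
    null_lists: random lists per null model (B).
    threshold / threshold_mode: expressed-gene cut; ``absolute`` keeps
        values > threshold (TPM-like data), ``quantile`` keeps values above
        the per-sample quantile (intensity data).
    universe: ``atlas`` draws null lists from the reference gene list,
        ``query`` restricts to genes measured in the query.
    rank_direction: signature ranking by specificity index; ``ascending``
        selects the most specific genes (smallest S).
    alpha: significance level for detection limits.
    welch: use Welch's t instead of pooled-variance Student's t.
    seed: master seed for all Monte-Carlo draws.
    """

    signature_size: int = 80
    null_lists: int = 1000
    threshold: float = 1.0
    threshold_mode: str = "absolute"
    universe: str = "atlas"
    rank_direction: str = "ascending"
    alpha: float = 0.05
    welch: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.signature_size < 1:
            raise ValueError("signature_size must be positive")
        if self.null_lists < 1:
            raise ValueError("null_lists must be positive")
        if self.threshold_mode not in ("absolute", "quantile"):
            raise ValueError(f"unknown threshold_mode: {self.threshold_mode!r}")
        if self.universe not in ("atlas", "query"):
            raise ValueError(f"unknown universe mode: {self.universe!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Short content hash identifying the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
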