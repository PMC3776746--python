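"""Declarative run configuration: every tunable in one place, always logged."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

logger = logging.getLogger("ahmo")

__all__ = ["AhmoConfig"]


@dataclass
class AhmoConfig:
    """All pipeline tunables with their defaults.

    Attributes
    ----------
    n_drop : initial scans discarded for scanner stabilization.
    low_hz, high_hz : band-pass edges in Hz.
    ns : temporal sample size used for z standardization (scans kept).
    threshold_z : network-forming threshold on standardized weights.
    min_size : smallest allowed cluster in voxels (acquisition-resolution
        default; scale for toy grids).
    connectivity : spatial adjacency for contiguity repair (6, 18 or 26).
    restarts : modularity-optimizer restarts.
    seed : master RNG seed; all stage seeds derive from it.
    """

    n_drop: int = 5
    low_hz: float = 0.009
    high_hz: float = 0.08
    ns: int = 160
    threshold_z: float = 3.0
    min_size: int = 50
    connectivity: int = 6
    restarts: int = 20
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AhmoConfig":
        raw = json.loads(Path(path).read_text())
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def log_resolved(self) -> dict:
        resolved = asdict(self)
        logger.info("resolved config: %s", json.dumps(resolved, sort_keys=True))
        return resolved
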