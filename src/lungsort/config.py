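"""Analysis configuration and seeded stage-wise random streams."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .errors import ValidationError

__all__ = ["AnalysisConfig", "stage_rng"]

_METRICS = ("manhattan", "bray_curtis")



@dataclass
class AnalysisConfig:
    """Knobs shared by the filtering and statistics stages.

    ``pseudocount`` of ``None`` means the data-driven default: half the
    smallest nonzero relative abundance in the table being transformed.
    ``alr_reference`` is either the ``"remainder"`` policy (each taxon
    against the 1 - x_i pseudo-component) or a fixed taxon name.
    """

    pseudocount: float | None = None
    distance_metric: str = "manhattan"
    n_permutations: int = 999
    nmds_dimensions: int = 2
    nmds_restarts: int = 8
    rng_seed: int = 0
    alr_reference: str = "remainder"
    p_grid_resolution: float = 1e-3

    def __post_init__(self) -> None:
        if self.pseudocount is not None and not self.pseudocount > 0:
            raise ValidationError("pseudocount must be > 0 (or None for the data-driven default)")
        if self.distance_metric not in _METRICS:
            raise ValidationError(f"distance_metric must be one of {_METRICS}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.nmds_dimensions < 1:
            raise ValidationError("nmds_dimensions must be >= 1")
        if self.nmds_restarts < 1:
            raise ValidationError("nmds_restarts must be >= 1")
        if not (0 < self.p_grid_resolution <= 0.1):
            raise ValidationError("p_grid_resolution must lie in (0, 0.1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.rng_seed, stage)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named pipeline stage.

    Derived from the global seed plus a stable hash of the stage name, so
    adding or reordering stages never perturbs another stage's draws.
    """
    entropy = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), entropy]))
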