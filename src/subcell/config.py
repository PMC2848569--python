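"""Run configuration shared by the feature builders, engines and CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .annotations import FUND_DIMENSION, GO_DIMENSION


@dataclass
class RunConfig:
    """All tunable parameters of the prediction pipeline.

    Thresholds
    ----------
    identity_min : minimum BLAST percent identity for the homology set (%).
    evalue_max_go / evalue_max_fund : inclusive expect-value cutoffs for the
        homolog search and the domain hits.

    Engine
    ------
    alpha : evidential mass ceiling in (0, 1).
    theta : multi-label vote-share band width in [0, 1).
    k_min..k_max : nearest-neighbor counts of the ensemble members (⊆ 1..10).
    xi_max : largest pseudo-PSSM lag (⊆ 0..49).
    space_weight : convex weight of the domain block in the combined space.
    """

    identity_min: float = 60.0
    evalue_max_go: float = 1e-3
    evalue_max_fund: float = 1e-3
    alpha: float = 0.95
    theta: float = 0.2
    k_min: int = 1
    k_max: int = 10
    xi_max: int = 49
    space_weight: float = 0.5
    go_dimension: int = GO_DIMENSION
    fund_dimension: int = FUND_DIMENSION
    mass_exponent: float = 2.0
    coupling_exponent: float = 2.0
    normalized_dempster: bool = True
    joint_space: bool = True
    refine_gammas: bool = False
    scoring_mode: str = "locative"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max <= 10):
            raise ValueError("K range must be contained in [1, 10]")
        if not (0 <= self.xi_max <= 49):
            raise ValueError("xi range must be contained in [0, 49]")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scoring_mode not in ("locative", "penalized"):
            raise ValueError("scoring_mode must be 'locative' or 'penalized'")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)
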