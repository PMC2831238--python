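"""Run configuration: every tunable with its default, YAML round-trip, and
the master-seed fan-out used to keep pipeline stages independently
reproducible."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed"]

_MODES = ("real_pathway", "fully_connected", "pathway_blind")
_RANKINGS = ("abs_delta_j", "literal_delta_j")
_SEED_METHODS = ("mutual_information", "marginal_power")


@dataclass
class RunConfig:
    """All tunables of a selection run.

    t: candidate-set size per iteration. K: bootstrap subset count.
    fraction: per-subset share of the training data. N: ranking length and
    position-weight scale. p: expected unresolved-pair influence.
    decay_base: per-hop influence attenuation. n_bins: mutual-information
    discretisation. regularization: SVM box constraint C.
    """

    t: int = 10
    K: int = 50
    fraction: float = 0.8
    N: int = 150
    p: float = 0.0088
    decay_base: float = 2.0
    no_path_influence: float = 0.0
    n_bins: int = 10
    regularization: float = 1.0
    seed: int = 0
    mode: str = "real_pathway"
    ranking: str = "abs_delta_j"
    seed_method: str = "mutual_information"
    standardize: bool = False
    with_replacement: bool = False
    split_ratio: float = 0.8
    total_genes: int = 20500

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.ranking not in _RANKINGS:
            raise ValueError(f"ranking must be one of {_RANKINGS}")
        if self.seed_method not in _SEED_METHODS:
            raise ValueError(f"seed_method must be one of {_SEED_METHODS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the resolved config, stamped on outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def literal_delta_j_order(self) -> bool:
        return self.ranking == "literal_delta_j"


def stage_seed(master_seed: int, stage: int) -> int:
    """Derive an independent sub-seed for pipeline stage ``stage``.

    Uses a spawned SeedSequence so stages never share streams; the result
    stays below 2^31 so it is safe for any generator.
    """
    return int(np.random.SeedSequence([master_seed, stage]).generate_state(1)[0] % (2**31))
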