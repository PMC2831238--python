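"""Bootstrap rank aggregation.

The forward selection is run on K stratified subsets of the training data;
the K rankings are stored as a K × N matrix of feature ids, a feature at
1-based column k of a row earns weight N − k, and weights are summed over
rows. The N highest-weight features form the final ranking, favouring
features that appear often and early.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, bootstrap_subsets
from .pathway import GeneMapping, InfluenceModel, PathwayGraph
from .selection import bpfs_select

__all__ = [
    "WeightMatrix",
    "build_weight_matrix",
    "feature_weight",
    "aggregate",
    "run_ensemble",
]


@dataclass
class WeightMatrix:
    """K × N matrix of per-subset rankings (row i = first N features of
    subset i's ranking); N doubles as the position-weight scale."""

    entries: list[list[str]]
    N: int

    @property
    def K(self) -> int:
        return len(self.entries)

    def save(self, path) -> None:
        pd.DataFrame(self.entries).to_csv(path, sep="\t", header=False, index=False)

    @staticmethod
    def load(path) -> "WeightMatrix":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        entries = df.values.tolist()
        return WeightMatrix(entries, N=len(entries[0]))


def build_weight_matrix(rankings: Sequence[Sequence[str]], N: int) -> WeightMatrix:
    """Truncate each of the K rankings to its first N entries."""
    entries = []
    for i, ranking in enumerate(rankings):
        if len(ranking) < N:
            raise ValueError(f"ranking from subset {i} has {len(ranking)} < N={N} entries")
        row = list(ranking[:N])
        if len(set(row)) != N:
            raise ValueError(f"ranking from subset {i} contains duplicates")
        entries.append(row)
    return WeightMatrix(entries, N=N)


def feature_weight(matrix: WeightMatrix, feature: str) -> int:
    """Sum of N − k over every occurrence at 1-based column k; 0 if absent."""
    total = 0
    for row in matrix.entries:
        for k, feat in enumerate(row, start=1):
            if feat == feature:
                total += matrix.N - k
    return total


def aggregate(matrix: WeightMatrix, output_count: int) -> list[tuple[str, int]]:
    """Features sorted by total weight descending.

    Ties break by the earliest (smallest) column at which the feature ever
    appears, then lexicographic feature id. Returns (feature, weight) pairs.
    """
    weights: dict[str, int] = {}
    best_col: dict[str, int] = {}
    for row in matrix.entries:
        for k, feat in enumerate(row, start=1):
            weights[feat] = weights.get(feat, 0) + matrix.N - k
            if k < best_col.get(feat, matrix.N + 1):
                best_col[feat] = k
    if output_count > len(weights):
        warnings.warn(
            f"output_count={output_count} exceeds {len(weights)} distinct features; returning all"
        )
        output_count = len(weights)
    ranked = sorted(weights, key=lambda f: (-weights[f], best_col[f], f))
    return [(f, weights[f]) for f in ranked[:output_count]]


def run_ensemble(
    data: ExpressionMatrix,
    graph: PathwayGraph | None,
    mapping: GeneMapping | None,
    model: InfluenceModel,
    K: int = 50,
    fraction: float = 0.8,
    N: int = 150,
    t: int = 10,
    seed: int = 0,
    regularization: float = 1.0,
    seed_method: str = "mutual_information",
    n_bins: int = 10,
    literal_delta_j_order: bool = False,
    with_replacement: bool = False,
) -> list[tuple[str, int]]:
    """Bootstrap-aggregate the forward selection: K subsets → K rankings of
    length N → weight matrix → final N-feature ranking. Deterministic under
    ``seed``."""
    if N > data.n_features:
        raise ValueError(f"N={N} exceeds {data.n_features} features")
    subsets = bootstrap_subsets(data, K, fraction, seed, with_replacement=with_replacement)
    rankings = []
    for i, idx in enumerate(subsets):
        sub = data.subset_samples(idx)
        try:
            ranking, _ = bpfs_select(
                sub,
                graph,
                mapping,
                model,
                target_count=N,
                t=t,
                regularization=regularization,
                seed_method=seed_method,
                n_bins=n_bins,
                literal_delta_j_order=literal_delta_j_order,
            )
        except Exception as exc:
            raise RuntimeError(f"selection failed on subset {i}") from exc
        rankings.append(ranking)
    matrix = build_weight_matrix(rankings, N)
    return aggregate(matrix, N)
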