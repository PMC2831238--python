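"""Synthetic two-class expression data with planted redundant blocks, and
matching modular pathway graphs with a configurable unmappable fraction.

Informative features come in blocks that are (a) statistically redundant —
correlated through a shared per-sample latent factor — and (b) biologically
redundant — wired as connected subgraphs (cliques by default) of the
generated pathway. This is exactly the regime the pathway-aware selection
is meant to exploit: a pathway-blind forward pass tends to pick several
members of one strong block, while the influence penalty pushes later picks
into unexplored blocks.

The correlation construction is x = μ_class + √ρ·z_block + √(1−ρ)·ε with
z, ε standard normal, giving pairwise within-block correlation ρ (before
the mean shift) and unit marginal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix
from .pathway import UNRESOLVED, GeneMapping, PathwayGraph

__all__ = ["SyntheticSpec", "generate_expression", "generate_pathway", "fig1_fixture"]


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of a synthetic study.

    effect_size is the between-class mean gap of informative features in
    noise-SD units; unresolved_fraction is the share of features that cannot
    be mapped to a pathway gene (default 0.6, the regime where most
    candidates lack a mapping); p_within / p_between are edge probabilities
    inside a block clique vs between blocks.
    """

    n_samples: int = 120
    n_features: int = 100
    n_blocks: int = 5
    block_size: int = 4
    effect_size: float = 1.5
    within_block_correlation: float = 0.8
    unresolved_fraction: float = 0.6
    p_within: float = 1.0
    p_between: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks * self.block_size > self.n_features:
            raise ValueError("informative blocks exceed n_features")
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must be in [0,1)")
        for name in ("unresolved_fraction", "p_within", "p_between"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")

    @property
    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features - 1))
        return [f"f{i:0{width}d}" for i in range(self.n_features)]


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, int | None]]:
    """Draw a balanced two-class matrix with planted informative blocks.

    Returns the matrix and the ground truth: feature id → block index for
    informative features, None for pure-noise features. Block b occupies
    features [b·block_size, (b+1)·block_size). Bit-reproducible under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features
    n_pos = n // 2
    labels = np.array([-1] * (n - n_pos) + [1] * n_pos)
    rho = spec.within_block_correlation

    X = rng.standard_normal((n, m))
    truth: dict[str, int | None] = {}
    ids = spec.feature_ids
    for j, fid in enumerate(ids):
        truth[fid] = None
    for b in range(spec.n_blocks):
        z = rng.standard_normal(n)  # shared latent factor of block b
        for j in range(b * spec.block_size, (b + 1) * spec.block_size):
            X[:, j] = (
                labels * spec.effect_size / 2
                + np.sqrt(rho) * z
                + np.sqrt(1 - rho) * X[:, j]
            )
            truth[ids[j]] = b

    width = len(str(n - 1))
    sample_ids = [f"s{i:0{width}d}" for i in range(n)]
    data = ExpressionMatrix(sample_ids, ids, X, labels)
    return data, truth


def generate_pathway(
    spec: SyntheticSpec, feature_ids: list[str] | None = None
) -> tuple[PathwayGraph, GeneMapping]:
    """Build the pathway graph and feature→gene mapping matching a spec.

    Each informative block becomes a connected subgraph: a spanning path
    guarantees connectivity and every remaining intra-block pair gets an
    edge with probability p_within. Pairs of genes in different blocks (or
    involving non-block genes) get background edges with probability
    p_between. A uniform ``unresolved_fraction`` of features is marked
    UNRESOLVED; only resolved features' genes become vertices.
    """
    if feature_ids is None:
        feature_ids = spec.feature_ids
    rng = np.random.default_rng(spec.seed + 1)

    resolved = rng.random(len(feature_ids)) >= spec.unresolved_fraction
    mapping = {
        fid: (f"g_{fid}" if ok else UNRESOLVED) for fid, ok in zip(feature_ids, resolved)
    }
    gene_of = {fid: g for fid, g in mapping.items() if g != UNRESOLVED}

    block_of = {}
    for b in range(spec.n_blocks):
        for j in range(b * spec.block_size, (b + 1) * spec.block_size):
            block_of[feature_ids[j]] = b

    g = nx.Graph()
    g.add_nodes_from(gene_of.values())
    genes = sorted(gene_of.items())  # (feature, gene), deterministic order
    # intra-block wiring: spanning path + Bernoulli(p_within) extra edges
    for b in range(spec.n_blocks):
        members = [gene for fid, gene in genes if block_of.get(fid) == b]
        for a, c in zip(members, members[1:]):
            g.add_edge(a, c)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < spec.p_within:
                    g.add_edge(members[i], members[j])
    # background wiring across blocks / noise genes
    if spec.p_between > 0:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                fi, gi = genes[i]
                fj, gj = genes[j]
                same_block = (
                    block_of.get(fi) is not None and block_of.get(fi) == block_of.get(fj)
                )
                if not same_block and rng.random() < spec.p_between:
                    g.add_edge(gi, gj)

    return PathwayGraph(g), GeneMapping(mapping)


#: Edges of the worked-example signalling subgraph: PKB/Akt phosphorylates
#: CASP9, BAD and IKK; IKK activates NFkB; BAD sequesters Bcl-xl; RacGEF
#: activates RAC, which activates NFkB.
FIG1_EDGES = [
    ("PKB/Akt", "CASP9"),
    ("PKB/Akt", "IKK"),
    ("IKK", "NFkB"),
    ("PKB/Akt", "BAD"),
    ("BAD", "Bcl-xl"),
    ("RacGEF", "RAC"),
    ("RAC", "NFkB"),
]


def fig1_fixture() -> tuple[PathwayGraph, GeneMapping]:
    """The small apoptosis/NFkB signalling subgraph used as a worked example,
    with an identity mapping (every gene resolved)."""
    g = nx.Graph()
    g.add_edges_from(FIG1_EDGES)
    graph = PathwayGraph(g)
    return graph, GeneMapping.all_resolved(graph.vertices)
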