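"""Consolidated interaction graph, hop-distance influence metrics, and the
probabilistic model for features that cannot be mapped onto the graph.

Influence between two mapped genes decays geometrically in their shortest
hop distance d: IF = 1/base^(d−1), so a direct interaction scores 1 and each
extra hop halves the influence (default base 2). The Total Influence Factor
(TIF) of a candidate against an already-selected set sums the pairwise IFs;
unmapped ("unresolved") features contribute a constant expected influence p
per pair. p itself is estimated by subsampling graph edges, fitting a
saturating curve to average reachability, extrapolating to the hypothetical
complete graph, and dividing by the total gene count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "NO_PATH",
    "UNRESOLVED",
    "PathwayGraph",
    "GeneMapping",
    "InfluenceModel",
    "ReachabilityCurve",
    "consolidate",
    "hop_distance",
    "influence_factor",
    "total_influence",
    "fully_connected_graph",
    "subsample_edges",
    "average_reachability",
    "fit_reachability_curve",
    "estimate_p",
]

#: Sentinel returned by :func:`hop_distance` for disconnected pairs.
NO_PATH = math.inf

#: Marker used in mapping tables for features with no pathway gene.
UNRESOLVED = "UNRESOLVED"


@dataclass
class PathwayGraph:
    """Undirected gene-interaction graph (no self-loops).

    ``pathway_membership`` is only populated in the fully-connected variant,
    where it records which pathway clique(s) each gene belongs to.
    """

    graph: nx.Graph
    pathway_membership: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class GeneMapping:
    """Feature id → pathway gene id, or UNRESOLVED for unmappable features."""

    mapping: dict[str, str]

    def gene(self, feature_id: str) -> str:
        try:
            return self.mapping[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} absent from mapping") from None

    def is_resolved(self, feature_id: str) -> bool:
        return self.gene(feature_id) != UNRESOLVED

    @staticmethod
    def all_resolved(feature_ids: Iterable[str]) -> "GeneMapping":
        """Identity mapping: every feature id is its own gene id."""
        return GeneMapping({f: f for f in feature_ids})

    @staticmethod
    def load(path) -> "GeneMapping":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        return GeneMapping(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def save(self, path) -> None:
        pd.DataFrame(sorted(self.mapping.items())).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class InfluenceModel:
    """Parameters of the influence metric.

    decay_base > 1 controls the per-hop attenuation (IF = base^(1−d));
    p is the expected influence of an unresolved pairing; disconnected
    mapped pairs contribute ``no_path_influence`` (0 keeps the decay
    monotone: farther can never mean stronger).
    """

    decay_base: float = 2.0
    p: float = 0.0088
    no_path_influence: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_base <= 1:
            raise ValueError("decay_base must be > 1")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0,1]")
        if self.no_path_influence < 0:
            raise ValueError("no_path_influence must be >= 0")


def consolidate(edge_tables: Sequence) -> PathwayGraph:
    """Merge edge lists into one undirected graph (set union of edges).

    Each table is a path to a 2- or 3-column TSV (SIF-style middle
    interaction column tolerated) or an iterable of gene-id pairs.
    Duplicate edges collapse; self-loops are dropped but keep their vertex.
    """
    g = nx.Graph()
    for table in edge_tables:
        if isinstance(table, (str, bytes)) or hasattr(table, "read") or _is_path(table):
            df = pd.read_csv(table, sep="\t", header=None, comment="#", dtype=str)
            if df.shape[1] >= 3:  # SIF: source, interaction, target
                pairs = zip(df.iloc[:, 0], df.iloc[:, 2])
            else:
                pairs = zip(df.iloc[:, 0], df.iloc[:, 1])
        else:
            pairs = table
        for a, b in pairs:
            if a == b:
                g.add_node(a)
            else:
                g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise ValueError("edge tables produced an empty graph")
    return PathwayGraph(g)


def _is_path(obj) -> bool:
    import os

    return isinstance(obj, os.PathLike)


def hop_distance(graph: PathwayGraph, g1: str, g2: str):
    """Shortest-path length in edges between two genes; NO_PATH if disconnected."""
    for g in (g1, g2):
        if g not in graph.graph:
            raise KeyError(f"gene {g!r} not in graph")
    try:
        return nx.shortest_path_length(graph.graph, g1, g2)
    except nx.NetworkXNoPath:
        return NO_PATH


def influence_factor(model: InfluenceModel, graph: PathwayGraph, g1: str, g2: str) -> float:
    """Pairwise influence base^(1−d); ``no_path_influence`` when disconnected."""
    if g1 == g2:
        raise ValueError("influence_factor is undefined for identical genes")
    d = hop_distance(graph, g1, g2)
    if d == NO_PATH:
        return model.no_path_influence
    return model.decay_base ** (1 - d)


def total_influence(
    model: InfluenceModel,
    graph: PathwayGraph,
    mapping: GeneMapping,
    candidate: str,
    selected: Sequence[str],
) -> float:
    """Total Influence Factor of a candidate feature against the selected set.

    Resolved candidate: p·|Q| + Σ IF over the resolved members R, where Q is
    the unresolved part of ``selected``. Unresolved candidate: p·|S|.
    Two features mapping to the same gene count as distance 0 (influence
    base^1, the maximum of the decay).
    """
    if candidate in selected:
        raise ValueError(f"candidate {candidate!r} already selected")
    if not selected:
        return 0.0
    if not mapping.is_resolved(candidate):
        return model.p * len(selected)
    cand_gene = mapping.gene(candidate)
    tif = 0.0
    for feat in selected:
        if not mapping.is_resolved(feat):
            tif += model.p
            continue
        sel_gene = mapping.gene(feat)
        if sel_gene == cand_gene:
            tif += model.decay_base  # d = 0: same pathway gene
        elif cand_gene not in graph or sel_gene not in graph:
            # mapped but absent from the interaction tables: no path
            tif += model.no_path_influence
        else:
            tif += influence_factor(model, graph, cand_gene, sel_gene)
    return tif


def fully_connected_graph(
    membership: Mapping[str, str | Iterable[str]],
    all_genes: Iterable[str] = (),
) -> PathwayGraph:
    """Idealised variant: each pathway is a clique, pathways share no edges.

    ``membership`` maps gene id → pathway id (or several). Genes listed in
    ``all_genes`` but absent from the membership become isolated vertices
    (singleton pathways). A gene in several pathways joins every one of its
    cliques; no edge is added between genes sharing no pathway.
    """
    by_pathway: dict[str, set[str]] = {}
    gene_pathways: dict[str, set[str]] = {}
    for gene, pw in membership.items():
        pws = {pw} if isinstance(pw, str) else set(pw)
        gene_pathways[gene] = pws
        for p in pws:
            by_pathway.setdefault(p, set()).add(gene)
    g = nx.Graph()
    g.add_nodes_from(gene_pathways)
    g.add_nodes_from(all_genes)
    for members in by_pathway.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
    return PathwayGraph(g, pathway_membership=gene_pathways)


def subsample_edges(graph: PathwayGraph, fraction: float, seed: int) -> PathwayGraph:
    """Keep round(fraction·|E|) uniformly chosen edges; vertex set unchanged."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    edges = sorted(tuple(sorted(e)) for e in graph.graph.edges)
    n_keep = int(round(fraction * len(edges)))
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(edges), size=n_keep, replace=False) if edges else []
    sub = nx.Graph()
    sub.add_nodes_from(graph.graph.nodes)
    sub.add_edges_from(edges[i] for i in sorted(keep_idx))
    return PathwayGraph(sub, pathway_membership=graph.pathway_membership)


def average_reachability(graph: PathwayGraph) -> float:
    """Mean over vertices of the number of OTHER vertices reachable from each.

    Every vertex of a connected component of size c reaches c−1 others, so
    the mean is Σ |C_i|·(|C_i|−1) / |V| over components.
    """
    n = graph.graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph has no vertices")
    total = sum(len(c) * (len(c) - 1) for c in nx.connected_components(graph.graph))
    return total / n


@dataclass
class ReachabilityCurve:
    """Average reachability vs edge-retention fraction, with a fitted
    saturating curve f(s) = A − B·q^s whose asymptote A estimates the
    reachability of the hypothetical complete graph."""

    fractions: np.ndarray
    reachabilities: np.ndarray
    asymptote: float
    amplitude: float
    ratio: float
    residuals: np.ndarray = field(default=None)
    extrapolation_limit: float | None = None

    def __call__(self, s) -> np.ndarray:
        return self.asymptote - self.amplitude * self.ratio ** np.asarray(s, dtype=float)

    def save(self, path) -> None:
        pd.DataFrame(
            {
                "s": self.fractions,
                "R_Ps": self.reachabilities,
                "fitted": self(self.fractions),
            }
        ).to_csv(path, sep="\t", index=False)


def fit_reachability_curve(fractions, reachabilities) -> ReachabilityCurve:
    """Least-squares fit of f(s) = A − B·q^s with A,B > 0 and 0 < q < 1.

    ``fractions`` are percentages of retained edges (e.g. 10, 20, …, 100);
    at least 4 strictly increasing points are required. Raises RuntimeError
    with diagnostics if the optimiser fails.
    """
    s = np.asarray(fractions, dtype=float)
    r = np.asarray(reachabilities, dtype=float)
    if len(s) < 4:
        raise ValueError("at least 4 points required")
    if np.any(np.diff(s) <= 0):
        raise ValueError("fractions must be strictly increasing")
    if np.any(r < 0):
        raise ValueError("reachabilities must be nonnegative")

    def f(x, A, B, q):
        return A - B * q**x

    rmax = max(r.max(), 1e-9)
    # saturated (near-constant) data: analytic shortcut, B ~ 0
    if np.ptp(r) < 1e-12:
        curve = ReachabilityCurve(s, r, asymptote=float(r.mean()), amplitude=0.0, ratio=0.5)
        curve.residuals = r - curve(s)
        return curve
    p0 = (rmax * 1.1, max(rmax * 1.1 - r[0], 1e-6), 0.97)
    try:
        popt, _ = curve_fit(
            f,
            s,
            r,
            p0=p0,
            bounds=([1e-12, 1e-12, 1e-9], [np.inf, np.inf, 1 - 1e-9]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"reachability curve fit failed: {exc}; points s={s.tolist()}, r={r.tolist()}"
        ) from exc
    curve = ReachabilityCurve(
        s, r, asymptote=float(popt[0]), amplitude=float(popt[1]), ratio=float(popt[2])
    )
    curve.residuals = r - curve(s)
    return curve


def estimate_p(
    curve: ReachabilityCurve,
    total_genes: int,
    extrapolate_to: float | None = None,
) -> float:
    """Expected unresolved-pair influence: extrapolated reachability / total genes.

    Evaluates the fitted curve at ``extrapolate_to`` (a percentage > 100 for
    the hypothetical complete graph) or uses the asymptote A when unset;
    the ratio is clamped to [0, 1].
    """
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    reach = curve.asymptote if extrapolate_to is None else float(curve(extrapolate_to))
    if extrapolate_to is not None:
        curve.extrapolation_limit = extrapolate_to
    return float(min(1.0, max(0.0, reach / total_genes)))
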