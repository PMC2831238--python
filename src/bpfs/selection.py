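"""The forward-selection main loop.

Seed with the feature of maximum mutual information (or maximum marginal
power on the empty set), then repeat: rank the remaining features by
marginal classification power, take the top t as candidates, and admit the
candidate with the LOWEST total influence on the already-selected set —
i.e. the biologically least redundant of the statistically strongest.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix
from .pathway import GeneMapping, InfluenceModel, PathwayGraph, total_influence
from .scoring import fit_svm, mutual_information, rank_candidates

__all__ = ["select_seed", "bpfs_select"]


def select_seed(
    data: ExpressionMatrix,
    method: str = "mutual_information",
    n_bins: int = 10,
    regularization: float = 1.0,
) -> str:
    """Pick the first feature: argmax of mutual information with the label,
    or of marginal power against the empty set. Ties break by matrix order."""
    if method == "mutual_information":
        scores = np.array(
            [mutual_information(data.values[:, j], data.labels, n_bins) for j in range(data.n_features)]
        )
        return data.feature_ids[int(np.argmax(scores))]
    if method == "marginal_power":
        fit = fit_svm(data, (), regularization)
        ranked = rank_candidates(data, fit, (), data.feature_ids, t=1)
        return ranked[0][0]
    raise ValueError(f"unknown seed method {method!r}")


def bpfs_select(
    data: ExpressionMatrix,
    graph: PathwayGraph | None,
    mapping: GeneMapping | None,
    model: InfluenceModel,
    target_count: int,
    t: int = 10,
    regularization: float = 1.0,
    seed_method: str = "mutual_information",
    n_bins: int = 10,
    literal_delta_j_order: bool = False,
    retrain_per_candidate: bool = False,
) -> tuple[list[str], list[dict]]:
    """Run the pathway-aware forward selection loop.

    Passing ``graph=None`` (or ``mapping=None``) runs the pathway-blind
    variant: influence is identically zero and selection reduces to pure
    top-ΔJ forward selection.

    Returns the ordered selected features and a per-iteration candidate log
    (feature, ΔJ and influence of every candidate, plus the chosen one).
    """
    if not 1 <= target_count <= data.n_features:
        raise ValueError("target_count must be in [1, n_features]")
    if t < 1:
        raise ValueError("t must be >= 1")

    pathway_blind = graph is None or mapping is None
    seed_feature = select_seed(data, seed_method, n_bins=n_bins, regularization=regularization)
    selected = [seed_feature]
    log = [{"iteration": 0, "method": seed_method, "chosen": seed_feature, "candidates": []}]
    available = [f for f in data.feature_ids if f != seed_feature]

    while len(selected) < target_count:
        try:
            fit = fit_svm(data, selected, regularization)
        except Exception as exc:
            raise RuntimeError(
                f"SVM failed at iteration {len(selected)} with selected={selected}"
            ) from exc
        ranked = rank_candidates(
            data,
            fit,
            selected,
            available,
            t,
            literal_delta_j_order=literal_delta_j_order,
            retrain_per_candidate=retrain_per_candidate,
        )
        entries = []
        best = None
        for rank, (feat, dj) in enumerate(ranked):
            if pathway_blind:
                tif = 0.0
            else:
                tif = total_influence(model, graph, mapping, feat, selected)
            entries.append({"feature": feat, "delta_j": dj, "tif": tif, "rank": rank + 1})
            # min TIF wins; ties by better ΔJ rank (earlier in ranked order)
            if best is None or tif < best[0]:
                best = (tif, rank, feat, dj)
        chosen = best[2]
        selected.append(chosen)
        available.remove(chosen)
        log.append(
            {
                "iteration": len(selected) - 1,
                "chosen": chosen,
                "delta_j": best[3],
                "tif": best[0],
                "candidates": entries,
            }
        )
    return selected, log
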