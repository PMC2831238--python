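"""Per-feature discriminative scores: mutual information for seeding, and the
marginal change of the linear-SVM dual objective for forward selection.

The soft-margin linear SVM dual is

    J = Σ_i α_i − ½ Σ_ij α_i α_j y_i y_j x_i·x_j .

Holding the multipliers α fixed and appending a candidate column m changes
the kernel by x_im·x_jm, so the marginal classification power is

    ΔJ(m) = −½ (Σ_i α_i y_i x_im)² = −½ w_m² ,

the (negated, squared) primal weight the current machine would put on m.
Candidates are ranked by |ΔJ| — equivalently w_m² — so features the machine
would lean on hardest come first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from sklearn.svm import SVC

from .expression import ExpressionMatrix

__all__ = [
    "SvmFit",
    "mutual_information",
    "fit_svm",
    "marginal_power",
    "delta_j_scores",
    "rank_candidates",
]


@dataclass
class SvmFit:
    """A solved linear-SVM dual on a fixed feature subset."""

    alphas: np.ndarray  # per-sample Lagrange multipliers, α_i ≥ 0
    objective: float  # dual objective J at the solution
    support_indices: np.ndarray  # samples with α_i > 0
    regularization: float  # box constraint C
    features: tuple[str, ...]  # the subset the fit was produced on


def mutual_information(
    values: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    strategy: str = "width",
) -> float:
    """Plug-in mutual information I(F, L) between a feature and the class label.

    Values are discretised into ``n_bins`` bins (equal-width by default,
    equal-frequency with ``strategy="frequency"``); the labels are the second
    variable. Natural logarithm; 0·log0 terms contribute 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) < 2:
        raise ValueError("at least 2 samples required")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant")

    if np.ptp(values) == 0:
        bins = np.zeros(len(values), dtype=int)
    elif strategy == "width":
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
        bins = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    elif strategy == "frequency":
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
        bins = np.clip(np.digitize(values, edges[1:-1]), 0, len(edges) - 2)
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")

    label_codes = (labels > 0).astype(int)
    joint = np.zeros((bins.max() + 1, 2))
    np.add.at(joint, (bins, label_codes), 1.0)
    joint /= joint.sum()
    pf = joint.sum(axis=1, keepdims=True)
    pl = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pf * pl))
    return float(np.nansum(terms))


def dual_objective(alphas: np.ndarray, labels: np.ndarray, X: np.ndarray) -> float:
    """Evaluate the linear-kernel dual objective J from α, y and the data."""
    a = alphas * labels
    K = X @ X.T
    return float(alphas.sum() - 0.5 * a @ K @ a)


def fit_svm(
    data: ExpressionMatrix,
    feature_subset: Sequence[str],
    regularization: float = 1.0,
) -> SvmFit:
    """Solve the soft-margin linear-kernel dual on a feature subset.

    The empty subset is the degenerate all-zero kernel: the dual reduces to
    maximising Σα_i under 0 ≤ α_i ≤ C and Σα_i y_i = 0, whose uniform
    within-class optimum α_i = C·min(n+,n−)/n_{y_i} is used directly.
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    y = data.labels.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    features = tuple(feature_subset)

    if not features:
        n_pos = int((y > 0).sum())
        n_neg = int((y < 0).sum())
        n_min = min(n_pos, n_neg)
        alphas = np.where(y > 0, regularization * n_min / n_pos, regularization * n_min / n_neg)
        return SvmFit(
            alphas=alphas,
            objective=float(alphas.sum()),
            support_indices=np.flatnonzero(alphas > 0),
            regularization=regularization,
            features=features,
        )

    cols = [data.feature_index(f) for f in features]
    X = data.values[:, cols]
    clf = SVC(kernel="linear", C=regularization, tol=1e-6)
    clf.fit(X, y)
    alphas = np.zeros(len(y))
    # dual_coef_ holds α_i·y_i for the support vectors
    alphas[clf.support_] = np.abs(clf.dual_coef_[0])
    return SvmFit(
        alphas=alphas,
        objective=dual_objective(alphas, y, X),
        support_indices=np.flatnonzero(alphas > 1e-12),
        regularization=regularization,
        features=features,
    )


def marginal_power(
    data: ExpressionMatrix,
    fit: SvmFit,
    selected: Sequence[str],
    candidate: str,
) -> float:
    """ΔJ(m): dual objective with the candidate column appended (α held
    fixed) minus the objective on the selected set alone. Always ≤ 0.
    """
    if tuple(selected) != fit.features:
        raise ValueError("fit was not produced on the given selected set")
    if candidate in fit.features:
        raise ValueError(f"candidate {candidate!r} already selected")
    a = fit.alphas * data.labels
    xm = data.column(candidate)
    # appending m adds x_im·x_jm to the kernel: J_new − J = −½ (a·x_m)²
    augmented = fit.objective - 0.5 * float(a @ xm) ** 2
    return augmented - fit.objective


def delta_j_scores(
    data: ExpressionMatrix,
    fit: SvmFit,
    available: Sequence[str],
) -> np.ndarray:
    """Vectorised ΔJ(m) = −½(Σα_i y_i x_im)² over the available features."""
    a = fit.alphas * data.labels
    cols = [data.feature_index(f) for f in available]
    w = a @ data.values[:, cols]
    return -0.5 * w**2


def rank_candidates(
    data: ExpressionMatrix,
    fit: SvmFit,
    selected: Sequence[str],
    available: Sequence[str],
    t: int,
    literal_delta_j_order: bool = False,
    retrain_per_candidate: bool = False,
) -> list[tuple[str, float]]:
    """Top-t candidates by marginal classification power.

    Default order is |ΔJ| descending (most potential weight first); the
    ``literal_delta_j_order`` flag instead sorts by the signed ΔJ descending.
    ``retrain_per_candidate`` refits the SVM on selected ∪ {m} and uses the
    two-sided objective difference (slow; off by default). Ties break by
    position in ``available``. Returns (feature id, ΔJ) pairs.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    available = list(available)
    if not available:
        raise ValueError("no available features")
    if t > len(available):
        warnings.warn(f"t={t} exceeds {len(available)} available features; returning all")
        t = len(available)

    if retrain_per_candidate:
        scores = np.array(
            [
                fit_svm(data, list(selected) + [m], fit.regularization).objective
                - fit.objective
                for m in available
            ]
        )
    else:
        scores = delta_j_scores(data, fit, available)

    key = scores if literal_delta_j_order else np.abs(scores)
    # stable sort on negated key: descending score, ties by available-order
    order = np.argsort(-key, kind="stable")[:t]
    return [(available[i], float(scores[i])) for i in order]
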