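"""Partition-comparison metrics and view-matching evaluation protocols.

The central metric is the Hubert-Arabie adjusted Rand index (ARI): the
pair-counting agreement of two partitions, rescaled so that identical
partitions score 1 and independent random partitions score approximately 0.

Because the numbering of fitted views is arbitrary, object-cluster
recovery in a multi-view fit is scored by matching: for every true view,
the best ARI over all fitted views is taken, and those maxima are averaged
(a single fitted view may serve several true views).  View recovery itself
is scored as the ARI between the true and fitted feature-to-view
partitions, pooled over distribution families.
"""

from __future__ import annotations

import numpy as np


def _check_labels(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("partitions must contain at least one element")
    return a, b


def adjusted_rand(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    a, b = _check_labels(labels_a, labels_b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n_a, n_b = ai.max() + 1, bi.max() + 1
    contingency = np.zeros((n_a, n_b), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_cells = comb2(contingency).sum()
    sum_rows = comb2(contingency.sum(axis=1)).sum()
    sum_cols = comb2(contingency.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        # both partitions trivial (all-singletons or single cluster): identical
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def _fitted_object_partitions(fit):
    """Object partitions of the effective fitted views (n, V_eff)."""
    views = np.asarray(fit.effective_views)
    if views.size == 0:
        raise ValueError("fit has no effective views (no feature assigned anywhere)")
    return fit.map_Z[:, views]


def view_matched_object_ari(truth, fit) -> float:
    """Mean over true views of the best object-cluster ARI in the fit.

    For each true view, ARIs against every effective fitted view are
    computed and the maximum taken; the maxima are averaged over true
    views.  No assignment constraint is imposed: one fitted view may match
    several true views.
    """
    Z_true = np.asarray(truth.object_cluster_of_object)
    Z_fit = _fitted_object_partitions(fit)
    if Z_true.shape[0] != Z_fit.shape[0]:
        raise ValueError("object counts differ between truth and fit")
    best = [
        max(adjusted_rand(Z_true[:, t], Z_fit[:, v]) for v in range(Z_fit.shape[1]))
        for t in range(Z_true.shape[1])
    ]
    return float(np.mean(best))


def view_membership_ari(truth, fit) -> float:
    """ARI between true and MAP feature-to-view partitions, pooled over families."""
    true_labels = np.concatenate([np.asarray(v) for v in truth.view_of_feature])
    fit_labels = np.concatenate([np.asarray(v) for v in fit.map_view])
    return adjusted_rand(true_labels, fit_labels)


def perfect_view_count(truth, fit) -> int:
    """Number of true views whose feature set equals some fitted view's set.

    Features are pooled over families and indexed globally; a true view is
    counted only on exact set equality (the strictest reading of error-free
    view recovery -- merged or split views do not count).
    """
    true_labels = np.concatenate([np.asarray(v) for v in truth.view_of_feature])
    fit_labels = np.concatenate([np.asarray(v) for v in fit.map_view])
    true_sets = {
        v: frozenset(np.flatnonzero(true_labels == v).tolist())
        for v in np.unique(true_labels)
    }
    fit_sets = {
        frozenset(np.flatnonzero(fit_labels == v).tolist())
        for v in np.unique(fit_labels)
    }
    return sum(1 for s in true_sets.values() if s in fit_sets)


def ari_permutation_test(labels_a, labels_b, n_perm: int = 999, rng=None) -> float:
    """Permutation p-value for the observed ARI.

    The second partition's labels are permuted uniformly; the p-value uses
    the add-one correction (1 + #{ARI_perm >= ARI_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a, b = _check_labels(labels_a, labels_b)
    observed = adjusted_rand(a, b)
    hits = 0
    for _ in range(n_perm):
        if adjusted_rand(a, rng.permutation(b)) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)
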