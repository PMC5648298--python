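"""Synthetic multi-view datasets with known cluster structure.

Three generators cover the simulation designs used to benchmark the
method:

* :func:`gen_conventional` -- a check-board design with three views, two
  feature clusters per view per family, and 2/3/4 object clusters in views
  1-3, mixing Gaussian, Poisson and binary categorical features;
* :func:`gen_many_views` -- 20 clearly separated Gaussian views on only 30
  objects (a stress test for view recovery);
* :func:`gen_subspace` -- subspace-structured Gaussian data in which three
  object clusters live on 4 relevant features each, either on disjoint
  feature blocks (Type 1) or a shared block (Type 2), against a
  standard-normal background.

Each generator returns a :class:`~mvcoclust.inference.DatasetBundle` and a
:class:`GroundTruth` with the generating labels.  Missing entries are
injected uniformly at random (missing at random by construction); the
original cell values are retained beneath the mask so the missing-data
invariance of the fit can be tested directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import DatasetBundle, FamilySlab

# Block parameter matrices of the conventional design: one matrix per view,
# rows = object clusters, columns = feature clusters.
CONVENTIONAL_GAUSS_MEANS = (
    ((0.0, 4.0), (1.0, 3.0)),
    ((0.0, 5.0), (1.0, 4.0), (2.0, 3.0)),
    ((0.0, 6.0), (1.0, 5.0), (2.0, 4.0), (3.0, 3.0)),
)
CONVENTIONAL_POISSON_RATES = (
    ((1.0, 2.0), (2.0, 1.0)),
    ((1.0, 3.0), (2.0, 2.0), (3.0, 1.0)),
    ((1.0, 4.0), (2.0, 3.0), (3.0, 2.0), (4.0, 1.0)),
)
CONVENTIONAL_BINARY_P = (
    ((0.1, 0.9), (0.1, 0.9)),
    ((0.1, 0.9), (0.5, 0.5), (0.9, 0.1)),
    ((0.1, 0.9), (0.4, 0.6), (0.6, 0.4), (0.9, 0.1)),
)
CONVENTIONAL_K_PER_VIEW = (2, 3, 4)

SUBSPACE_CLUSTER_MEANS = (0.0, 2.0, 3.0)


@dataclass
class GroundTruth:
    """Generating labels of a synthetic dataset.

    ``view_of_feature``/``feature_cluster_of_feature`` hold one label per
    column, per family slab (same order as the bundle).
    ``object_cluster_of_object`` is (n, n_views): the true object partition
    of every view.  ``block_params`` records the generating parameters.
    """

    view_of_feature: list
    feature_cluster_of_feature: list
    object_cluster_of_object: np.ndarray
    block_params: dict
    n_views: int


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def gen_conventional(n: int = 100, d_per_view: int = 50, missing_rate: float = 0.0,
                     rng=None):
    """Three-view check-board data mixing Gaussian, Poisson, binary features.

    Each family contributes ``d_per_view`` features to each of the three
    views (views are evenly assigned to features in order).  Feature- and
    object-cluster memberships are uniformly random.  Gaussian blocks have
    unit standard deviation; binary features are categorical with level 1
    drawn with the block's success probability.  ``missing_rate`` masks
    cells independently.
    """
    rng = _as_rng(rng)
    if n not in (20, 50, 100) or d_per_view not in (10, 50, 100) \
            or missing_rate not in (0.0, 0.1, 0.2):
        warnings.warn(
            "non-canonical factor level for the conventional design "
            f"(n={n}, d_per_view={d_per_view}, missing_rate={missing_rate})",
            stacklevel=2,
        )
    n_views = 3
    Z = np.column_stack(
        [rng.integers(0, K_v, size=n) for K_v in CONVENTIONAL_K_PER_VIEW]
    )

    d_m = n_views * d_per_view
    view_of_feature = np.repeat(np.arange(n_views), d_per_view)

    slabs, views_list, gclusters = [], [], []
    params_by_family = {
        "gaussian": CONVENTIONAL_GAUSS_MEANS,
        "poisson": CONVENTIONAL_POISSON_RATES,
        "categorical": CONVENTIONAL_BINARY_P,
    }
    for family, param in params_by_family.items():
        g_of_feature = rng.integers(0, 2, size=d_m)
        X = np.empty((n, d_m))
        for j in range(d_m):
            v = view_of_feature[j]
            theta = np.asarray(param[v])[Z[:, v], g_of_feature[j]]
            if family == "gaussian":
                X[:, j] = rng.normal(theta, 1.0)
            elif family == "poisson":
                X[:, j] = rng.poisson(theta)
            else:
                X[:, j] = (rng.random(n) < theta).astype(float)
        levels = [[0, 1]] * d_m if family == "categorical" else None
        slabs.append(FamilySlab(family, X, np.ones((n, d_m), dtype=bool),
                                levels=levels))
        views_list.append(view_of_feature.copy())
        gclusters.append(g_of_feature)

    bundle = DatasetBundle(slabs)
    truth = GroundTruth(views_list, gclusters, Z, params_by_family, n_views)
    if missing_rate > 0:
        bundle = inject_missing(bundle, missing_rate, rng)
    return bundle, truth


def gen_many_views(rng=None, n: int = 30, n_views: int = 20, d_per_view: int = 100):
    """Gaussian data with many clearly separated views.

    Views 1..19 split the objects 15/15 with cluster means (2v-1, 2v) and
    standard deviation 0.1; the object-to-cluster allocation is a fresh
    random permutation in every view.  The last view is pure standard
    normal noise (a single object cluster).  The data are meant to be
    fitted *without* standardization, so the views stay far apart.
    """
    rng = _as_rng(rng)
    half = n // 2
    Z = np.zeros((n, n_views), dtype=int)
    X = np.empty((n, n_views * d_per_view))
    for v in range(n_views - 1):
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[:half]] = 1
        Z[:, v] = labels
        means = np.where(labels == 0, 2 * (v + 1) - 1, 2 * (v + 1)).astype(float)
        cols = slice(v * d_per_view, (v + 1) * d_per_view)
        X[:, cols] = rng.normal(means[:, None], 0.1, size=(n, d_per_view))
    X[:, (n_views - 1) * d_per_view:] = rng.normal(0.0, 1.0, size=(n, d_per_view))

    view_of_feature = np.repeat(np.arange(n_views), d_per_view)
    bundle = DatasetBundle(
        [FamilySlab("gaussian", X, np.ones_like(X, dtype=bool))]
    )
    truth = GroundTruth(
        [view_of_feature],
        [np.zeros(n_views * d_per_view, dtype=int)],
        Z,
        {"means": "2v-1 / 2v, sd 0.1; last view N(0,1)"},
        n_views,
    )
    return bundle, truth


def gen_subspace(type_: int, precision: float = 1.0, rng=None,
                 n: int = 300, cluster_size: int = 100):
    """Subspace-structured Gaussian data: 3 clusters on 4 relevant features.

    Type 1: cluster c's relevant features are its own disjoint block of 4
    columns (columns 4c..4c+3) drawn N(mean_c, precision^-1/2); everything
    else is standard-normal background.  Type 2: all clusters share
    columns 0..3 (means 0/2/3); columns 4..11 are background.

    The evaluation target is the single 3-cluster object partition, so the
    ground truth carries one view; Type 1 feature clusters are the three
    blocks, Type 2 separates relevant from background features.
    """
    if type_ not in (1, 2):
        raise ValueError("subspace type must be 1 or 2")
    rng = _as_rng(rng)
    sd = 1.0 / np.sqrt(precision)
    d = 12
    labels = np.repeat(np.arange(3), cluster_size)
    X = rng.normal(0.0, 1.0, size=(n, d))
    if type_ == 1:
        for c, mean in enumerate(SUBSPACE_CLUSTER_MEANS):
            rows = labels == c
            X[np.ix_(rows, range(4 * c, 4 * c + 4))] = rng.normal(
                mean, sd, size=(rows.sum(), 4)
            )
        feature_cluster = np.repeat(np.arange(3), 4)
    else:
        for c, mean in enumerate(SUBSPACE_CLUSTER_MEANS):
            rows = labels == c
            X[np.ix_(rows, range(4))] = rng.normal(mean, sd, size=(rows.sum(), 4))
        feature_cluster = np.array([0] * 4 + [1] * 8)

    bundle = DatasetBundle([FamilySlab("gaussian", X, np.ones_like(X, dtype=bool))])
    truth = GroundTruth(
        [np.zeros(d, dtype=int)],
        [feature_cluster],
        labels[:, None],
        {"means": SUBSPACE_CLUSTER_MEANS, "precision": precision, "type": type_},
        1,
    )
    return bundle, truth


def inject_missing(bundle: DatasetBundle, rate: float, rng=None) -> DatasetBundle:
    """Mask each cell independently with probability ``rate``.

    Cell values are kept beneath the mask (they must never influence a
    fit; tests rely on that).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    rng = _as_rng(rng)
    slabs = []
    for slab in bundle.slabs:
        keep = rng.random(slab.X.shape) >= rate
        slabs.append(
            FamilySlab(slab.family, slab.X.copy(), slab.mask & keep,
                       columns=list(slab.columns), levels=slab.levels,
                       n_levels=slab.n_levels)
        )
    return DatasetBundle(slabs)
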