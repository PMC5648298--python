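"""Reading mixed-type data tables and writing fit artifacts.

A dataset is a CSV/TSV table (header row of feature names, one row per
object, empty cells or ``NA`` for missing values) plus a feature
specification mapping each column to a distribution family.  The spec is a
JSON list of per-column entries::

    [{"name": "age", "family": "gaussian", "standardize": true},
     {"name": "visits", "family": "poisson"},
     {"name": "smoker", "family": "categorical", "levels": ["no", "yes"]}]

Gaussian columns are standardized by default using observed-cell mean and
standard deviation.  Categorical level sets are frozen at load time: either
from an explicit ``levels`` list or by first appearance in the column.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import DatasetBundle, FamilySlab, FitResult

_FAMILY_ORDER = ("gaussian", "poisson", "categorical")


def _level_str(value) -> str:
    """Canonical string form of a categorical level.

    Integer-valued floats (as produced by pandas parsing a numeric column
    with missing cells) map to their integer spelling, so "1", 1 and 1.0
    all denote the same level.
    """
    if isinstance(value, (float, np.floating)) and float(value).is_integer():
        return str(int(value))
    return str(value)


def read_feature_spec(spec_path):
    spec = json.loads(Path(spec_path).read_text())
    for entry in spec:
        if "name" not in entry or "family" not in entry:
            raise ValueError("each feature-spec entry needs 'name' and 'family'")
        if entry["family"] not in _FAMILY_ORDER:
            raise ValueError(f"unknown family {entry['family']!r} for column {entry['name']!r}")
    return spec


def read_dataset(data_path, spec_path) -> DatasetBundle:
    """Load a CSV/TSV table into per-family slabs according to the spec."""
    data_path = Path(data_path)
    sep = "\t" if data_path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(data_path, sep=sep, na_values=["NA"], keep_default_na=True)
    spec = read_feature_spec(spec_path)

    for entry in spec:
        if entry["name"] not in df.columns:
            raise ValueError(f"spec column {entry['name']!r} not found in {data_path.name}")

    by_family = {fam: [] for fam in _FAMILY_ORDER}
    for entry in spec:
        by_family[entry["family"]].append(entry)

    slabs = []
    for family in _FAMILY_ORDER:
        entries = by_family[family]
        if not entries:
            continue
        n = len(df)
        X = np.empty((n, len(entries)))
        mask = np.empty((n, len(entries)), dtype=bool)
        levels_out = []
        for j, entry in enumerate(entries):
            col = df[entry["name"]]
            observed = col.notna().to_numpy()
            if not observed.any():
                raise ValueError(f"column {entry['name']!r} is entirely missing")
            mask[:, j] = observed
            if family == "categorical":
                raw = [_level_str(v) for v in col]
                seen = list(dict.fromkeys(v for v, ok in zip(raw, observed) if ok))
                declared = [_level_str(v) for v in entry.get("levels", seen)]
                unseen = set(seen) - set(declared)
                if unseen:
                    raise ValueError(
                        f"column {entry['name']!r} has levels {sorted(unseen)} "
                        "outside the declared level list"
                    )
                code = {lv: i for i, lv in enumerate(declared)}
                X[:, j] = [code[v] if ok else 0.0 for v, ok in zip(raw, observed)]
                levels_out.append(declared)
            else:
                values = pd.to_numeric(col, errors="coerce")
                bad = observed & values.isna().to_numpy()
                if bad.any():
                    raise ValueError(
                        f"non-numeric value in {family} column {entry['name']!r}"
                    )
                X[:, j] = values.fillna(0.0).to_numpy()
                if family == "gaussian" and entry.get("standardize", True):
                    mu = X[observed, j].mean()
                    sd = X[observed, j].std()
                    X[:, j] = (X[:, j] - mu) / (sd if sd > 0 else 1.0)
        slabs.append(
            FamilySlab(
                family, X, mask,
                columns=[e["name"] for e in entries],
                levels=levels_out if family == "categorical" else None,
            )
        )
    return DatasetBundle(slabs)


def write_fit(fit: FitResult, bundle: DatasetBundle, out_dir) -> dict:
    """Write feature/object tables, ELBO traces, and a run manifest.

    Returns the paths written.  ``features.csv`` maps every feature to its
    MAP (view, feature cluster); ``objects.csv`` holds the MAP object
    cluster per view; ``elbo_trace.csv`` is long-format per restart.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    feat_rows = []
    for slab, views, gs in zip(bundle.slabs, fit.map_view, fit.map_feature_cluster):
        for name, v, g in zip(slab.columns, views, gs):
            feat_rows.append({"feature": name, "family": slab.family,
                              "view": int(v), "feature_cluster": int(g)})
    features = pd.DataFrame(feat_rows)
    features.to_csv(out_dir / "features.csv", index=False)

    objects = pd.DataFrame(
        fit.map_Z, columns=[f"view_{v}" for v in range(fit.map_Z.shape[1])]
    )
    objects.insert(0, "object", np.arange(fit.map_Z.shape[0]))
    objects.to_csv(out_dir / "objects.csv", index=False)

    trace_rows = []
    for s, trace in enumerate(fit.elbo_traces):
        for it, value in enumerate(trace):
            trace_rows.append({"restart": s, "iteration": it, "elbo": value})
    pd.DataFrame(trace_rows).to_csv(out_dir / "elbo_trace.csv", index=False)

    manifest = {
        "seed": fit.trunc.seed,
        "truncation": {"V": fit.trunc.V, "G": fit.trunc.G, "K": fit.trunc.K,
                       "max_iter": fit.trunc.max_iter, "elbo_tol": fit.trunc.elbo_tol,
                       "n_restarts": fit.trunc.n_restarts},
        "prior": {k: getattr(fit.prior, k) for k in (
            "gaussian_m0", "gaussian_beta0", "gaussian_a0", "gaussian_b0",
            "poisson_a0", "poisson_b0", "dirichlet_alpha0",
            "alpha1", "alpha2", "beta_obj")},
        "best_restart": int(fit.best_restart),
        "final_elbo": fit.final_elbo,
        "effective_views": [int(v) for v in fit.effective_views],
        "n_effective_views": int(fit.n_effective_views),
        "restart_final_elbos": [float(t[-1]) for t in fit.elbo_traces],
        "restart_iterations": [int(len(t)) for t in fit.elbo_traces],
        "converged": [bool(c) for c in fit.converged],
        "categorical_levels": {
            slab.columns[j]: slab.levels[j]
            for slab in bundle.slabs if slab.family == "categorical" and slab.levels
            for j in range(len(slab.levels))
        },
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "features": out_dir / "features.csv",
        "objects": out_dir / "objects.csv",
        "elbo_trace": out_dir / "elbo_trace.csv",
        "manifest": out_dir / "manifest.json",
    }


def write_simulation(bundle: DatasetBundle, truth, out_dir) -> dict:
    """Write a simulated dataset as CSVs plus feature spec and truth labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    frames, spec, truth_rows = [], [], []
    for slab, views, gs in zip(bundle.slabs, truth.view_of_feature,
                               truth.feature_cluster_of_feature):
        values = slab.X.astype(object)
        if slab.family == "categorical":
            for j in range(slab.d):
                lv = slab.levels[j] if slab.levels else list(range(slab.n_levels))
                values[:, j] = [lv[int(c)] for c in slab.X[:, j]]
        values[~slab.mask] = np.nan
        frames.append(pd.DataFrame(values, columns=slab.columns))
        for j, name in enumerate(slab.columns):
            entry = {"name": name, "family": slab.family}
            if slab.family == "categorical" and slab.levels:
                entry["levels"] = [_level_str(v) for v in slab.levels[j]]
            spec.append(entry)
            truth_rows.append({"feature": name, "family": slab.family,
                               "view": int(views[j]), "feature_cluster": int(gs[j])})

    pd.concat(frames, axis=1).to_csv(out_dir / "data.csv", index=False, na_rep="NA")
    (out_dir / "feature_spec.json").write_text(json.dumps(spec, indent=2))
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth_features.csv", index=False)

    Z = pd.DataFrame(
        truth.object_cluster_of_object,
        columns=[f"view_{v}" for v in range(truth.object_cluster_of_object.shape[1])],
    )
    Z.insert(0, "object", np.arange(len(Z)))
    Z.to_csv(out_dir / "truth_objects.csv", index=False)
    return {"data": out_dir / "data.csv", "spec": out_dir / "feature_spec.json"}
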