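"""Simulation-study drivers: generate -> fit -> evaluate loops.

These functions reproduce the synthetic benchmarking protocol at a
configurable (usually reduced) scale: a factorial grid over the
conventional design's sample size, feature count and missing rate; the
many-views design; and the two subspace designs.  Each returns a tidy
DataFrame with one row per simulated dataset so factor-level means can be
taken directly.

All randomness derives from a single integer seed: dataset r of cell c
uses ``default_rng([seed, c, r])`` for generation and a distinct derived
seed for the fit restarts, so any run is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import perfect_view_count, view_matched_object_ari, view_membership_ari
from .inference import (
    PriorConfig,
    TruncationConfig,
    fit,
    preset_mode,
    standardize_gaussian,
)
from .synthetic import gen_conventional, gen_many_views, gen_subspace

# Truncation for the many-views design: the bound on views must exceed the
# 20 true views; clusters per view are small there (2 at most).
MANY_VIEWS_TRUNC = TruncationConfig(V=25, G=3, K=5)


def _fit_seed(seed: int, cell: int, rep: int) -> int:
    return (seed * 1_000_003 + cell * 101 + rep) % (2**31 - 1)


def run_conventional_grid(
    ns=(20, 50, 100),
    ds=(10, 50, 100),
    missing_rates=(0.0, 0.1, 0.2),
    replicates: int = 3,
    mode: str = "multiple_cocluster",
    trunc: TruncationConfig = None,
    prior: PriorConfig = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Factorial grid of the conventional design; one row per dataset.

    Gaussian columns are standardized before fitting (the usual
    preprocessing for this design); Poisson and categorical slabs are used
    as generated.
    """
    trunc = trunc or TruncationConfig()
    prior = prior or PriorConfig()
    rows = []
    cell = 0
    for n in ns:
        for d in ds:
            for rate in missing_rates:
                for rep in range(replicates):
                    rng = np.random.default_rng([seed, cell, rep])
                    bundle, truth = gen_conventional(n, d, rate, rng)
                    bundle = standardize_gaussian(bundle)
                    t = preset_mode(mode, trunc, d_total=bundle.d_total)
                    t = replace(t, seed=_fit_seed(seed, cell, rep))
                    result = fit(bundle, t, prior)
                    rows.append({
                        "n": n, "d_per_view": d, "missing_rate": rate,
                        "replicate": rep, "mode": mode,
                        "object_ari": view_matched_object_ari(truth, result),
                        "view_ari": view_membership_ari(truth, result),
                        "n_effective_views": result.n_effective_views,
                        "final_elbo": result.final_elbo,
                    })
                cell += 1
    return pd.DataFrame(rows)


def run_many_views(replicates: int = 5, trunc: TruncationConfig = None,
                   prior: PriorConfig = None, seed: int = 0) -> pd.DataFrame:
    """Replicates of the 20-view design, scored by perfect view recovery.

    The data are fitted without standardization (the views are separated
    by their means on purpose).
    """
    trunc = trunc or MANY_VIEWS_TRUNC
    prior = prior or PriorConfig()
    rows = []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        bundle, truth = gen_many_views(rng)
        t = replace(trunc, seed=_fit_seed(seed, 0, rep))
        result = fit(bundle, t, prior)
        rows.append({
            "replicate": rep,
            "perfect_views": perfect_view_count(truth, result),
            "object_ari": view_matched_object_ari(truth, result),
            "n_effective_views": result.n_effective_views,
        })
    return pd.DataFrame(rows)


def run_subspace(types=(1, 2), precisions=(1.0,), replicates: int = 10,
                 trunc: TruncationConfig = None, prior: PriorConfig = None,
                 seed: int = 0) -> pd.DataFrame:
    """Replicates of the subspace designs, scored by object-cluster ARI."""
    trunc = trunc or TruncationConfig()
    prior = prior or PriorConfig()
    rows = []
    cell = 0
    for type_ in types:
        for precision in precisions:
            for rep in range(replicates):
                rng = np.random.default_rng([seed, cell, rep])
                bundle, truth = gen_subspace(type_, precision, rng)
                bundle = standardize_gaussian(bundle)
                t = replace(trunc, seed=_fit_seed(seed, cell, rep))
                result = fit(bundle, t, prior)
                rows.append({
                    "type": type_, "precision": precision, "replicate": rep,
                    "object_ari": view_matched_object_ari(truth, result),
                    "n_effective_views": result.n_effective_views,
                })
            cell += 1
    return pd.DataFrame(rows)


def run_experiment(config_path, out_dir=None):
    """Run a design from a YAML config; write per-dataset and summary CSVs.

    The config names a design (``conventional`` | ``many_views`` |
    ``subspace``), its factor levels, the replicate count, truncation and
    prior overrides, and a seed.  Returns (per-dataset df, summary df).
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    design = cfg.get("design")
    seed = int(cfg.get("seed", 0))
    replicates = int(cfg.get("replicates", 3))
    trunc = TruncationConfig(**cfg.get("truncation", {}))
    prior = PriorConfig(**cfg.get("prior", {}))

    if design == "conventional":
        factors = cfg.get("factors", {})
        df = run_conventional_grid(
            ns=tuple(factors.get("n", (20, 50, 100))),
            ds=tuple(factors.get("d_per_view", (10, 50, 100))),
            missing_rates=tuple(factors.get("missing_rate", (0.0, 0.1, 0.2))),
            replicates=replicates,
            mode=cfg.get("mode", "multiple_cocluster"),
            trunc=trunc, prior=prior, seed=seed,
        )
        keys = ["n", "d_per_view", "missing_rate"]
        summary = df.groupby(keys)[["object_ari", "view_ari"]].mean().reset_index()
    elif design == "many_views":
        df = run_many_views(replicates=replicates, trunc=trunc, prior=prior, seed=seed)
        summary = df[["perfect_views", "object_ari"]].mean().to_frame().T
    elif design == "subspace":
        factors = cfg.get("factors", {})
        df = run_subspace(
            types=tuple(factors.get("type", (1, 2))),
            precisions=tuple(factors.get("precision", (1.0,))),
            replicates=replicates, trunc=trunc, prior=prior, seed=seed,
        )
        summary = df.groupby(["type", "precision"])["object_ari"].mean().reset_index()
    else:
        raise ValueError(f"unknown design {design!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "metrics.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
    return df, summary
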