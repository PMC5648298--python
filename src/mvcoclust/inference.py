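"""Truncated stick-breaking variational Bayes EM for multiple co-clustering.

The model partitions the columns of a mixed-type data matrix into *views*;
within each view, columns form feature clusters and the rows (objects) form
an object clustering specific to that view.  Every (view, feature-cluster,
object-cluster) block is fitted with an independent univariate conjugate
model (see :mod:`mvcoclust.observation`).  Feature allocation follows a
hierarchical stick-breaking prior (views, then feature clusters within a
view); object clusters follow a stick-breaking prior per view.  All stick
processes are truncated at finite lengths V, G, K in the variational
posterior.

Inference is mean-field coordinate ascent: conjugate block updates, Beta
stick updates, then multinomial responsibility updates for features (tau,
normalized over (feature-cluster, view) pairs) and for objects (eta,
normalized over clusters within each view).  Every update is the exact
maximizer of the evidence lower bound over its factor, so the ELBO is
non-decreasing across sweeps; the fit restarts from random initializations
and keeps the run with the highest final ELBO.

Missing entries are handled under a missing-at-random assumption by
zero-weighting masked cells in every sufficient statistic; the mask is the
only source of truth and masked cell values never influence any result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .observation import (
    BlockPosterior,
    PriorConfig,
    _psi,
    family_model,
    kl_beta,
)

_LOG_FLOOR = -700.0


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class FamilySlab:
    """One distribution family's data: an n x d matrix plus observed mask."""

    family: str
    X: np.ndarray          # (n, d); categorical stored as integer level codes
    mask: np.ndarray       # (n, d) bool, True = observed
    columns: list = None   # column names
    levels: list = None    # per-column level values (categorical only)
    n_levels: int = None   # size of the frozen level support (categorical)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.X.shape != self.mask.shape:
            raise ValueError(
                f"{self.family} slab: data shape {self.X.shape} != mask shape {self.mask.shape}"
            )
        if self.columns is None:
            self.columns = [f"{self.family}_{j}" for j in range(self.X.shape[1])]
        if self.family == "categorical" and self.n_levels is None:
            if self.levels is not None:
                self.n_levels = max(len(lv) for lv in self.levels)
            else:
                observed = self.X[self.mask]
                self.n_levels = int(observed.max()) + 1 if observed.size else 2

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def d(self):
        return self.X.shape[1]


@dataclass
class DatasetBundle:
    """Per-family data slabs sharing the same objects (rows)."""

    slabs: list

    def __post_init__(self):
        if not self.slabs:
            raise ValueError("DatasetBundle needs at least one family slab")
        n = self.slabs[0].n
        for slab in self.slabs:
            if slab.n != n:
                raise ValueError("all family slabs must share the same objects (rows)")
            if slab.d == 0:
                raise ValueError(f"{slab.family} slab has no columns")

    @property
    def n(self):
        return self.slabs[0].n

    @property
    def n_families(self):
        return len(self.slabs)

    @property
    def d_total(self):
        return sum(slab.d for slab in self.slabs)

    def validate_cells(self):
        """Check observed cells against their family's support."""
        for slab in self.slabs:
            obs = slab.X[slab.mask]
            if slab.family == "gaussian":
                if not np.all(np.isfinite(obs)):
                    raise ValueError("non-finite observed Gaussian cell")
            elif slab.family == "poisson":
                if obs.size and (obs.min() < 0 or not np.allclose(obs, np.rint(obs))):
                    raise ValueError("Poisson cells must be nonnegative integers")
            elif slab.family == "categorical":
                if obs.size:
                    codes = np.rint(obs)
                    if not np.allclose(obs, codes) or codes.min() < 0 or codes.max() >= slab.n_levels:
                        raise ValueError("categorical cell outside the frozen level support")
            else:
                raise ValueError(f"unknown family {slab.family!r}")


def standardize_gaussian(bundle: DatasetBundle) -> DatasetBundle:
    """Standardize each Gaussian column to observed mean 0 / sd 1.

    Non-Gaussian slabs pass through unchanged; columns with fewer than two
    observed cells, or zero observed variance, are left uncentred-scaled
    only as far as defined (sd treated as 1).
    """
    slabs = []
    for slab in bundle.slabs:
        if slab.family != "gaussian":
            slabs.append(slab)
            continue
        X = slab.X.copy()
        for j in range(slab.d):
            obs = slab.mask[:, j]
            if obs.sum() == 0:
                continue
            mu = X[obs, j].mean()
            sd = X[obs, j].std()
            X[:, j] = (X[:, j] - mu) / (sd if sd > 0 else 1.0)
        slabs.append(FamilySlab("gaussian", X, slab.mask.copy(), list(slab.columns)))
    return DatasetBundle(slabs)


@dataclass(frozen=True)
class TruncationConfig:
    """Truncation levels and optimizer settings.

    V, G, K are upper bounds on the numbers of views, feature clusters per
    view, and object clusters per view; the stick-breaking prior prunes
    unused components.  ``n_restarts`` random initializations are run and
    the best final ELBO kept.
    """

    V: int = 10
    G: int = 5
    K: int = 10
    max_iter: int = 500
    elbo_tol: float = 1e-6
    n_restarts: int = 20
    seed: int = 0

    def __post_init__(self):
        if min(self.V, self.G, self.K) < 1:
            raise ValueError("truncation levels V, G, K must be >= 1")
        if self.elbo_tol <= 0:
            raise ValueError("elbo_tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


@dataclass
class ResponsibilityState:
    """Variational multinomial parameters.

    ``tau[m]`` has shape (d_m, G, V): responsibility of feature j of family
    m for (feature-cluster g, view v), normalized over all (g, v) pairs.
    ``eta`` has shape (n, V, K): responsibility of object i for cluster k
    within view v, normalized over k for each (i, v).
    """

    tau: list
    eta: np.ndarray

    def validate(self, atol: float = 1e-10):
        for t in self.tau:
            if np.any(t < 0) or np.any(t > 1 + atol):
                raise ValueError("tau outside [0, 1]")
            if not np.allclose(t.sum(axis=(1, 2)), 1.0, atol=atol):
                raise ValueError("tau rows must sum to one over (g, v)")
        if not np.allclose(self.eta.sum(axis=2), 1.0, atol=atol):
            raise ValueError("eta must sum to one over k for each (i, v)")


@dataclass
class StickPosterior:
    """Beta posteriors of the view, feature-cluster, and object sticks.

    Arrays hold the two Beta parameters in the last axis: ``view`` (V, 2),
    ``feat[m]`` (G, V, 2) per family, ``obj`` (V, K, 2).
    """

    view: np.ndarray
    feat: list
    obj: np.ndarray


@dataclass
class FitResult:
    """MAP partitions, ELBO traces, and bookkeeping from :func:`fit`."""

    map_view: list            # per family: (d_m,) MAP view index of each feature
    map_feature_cluster: list  # per family: (d_m,) MAP feature-cluster index
    map_Z: np.ndarray          # (n, V) MAP object cluster per view
    elbo_traces: list          # per restart: np.ndarray of per-sweep ELBOs
    best_restart: int
    effective_views: np.ndarray  # view indices with >= 1 MAP-assigned feature
    n_object_clusters: np.ndarray  # (V,) distinct MAP object clusters per view
    converged: list
    responsibilities: ResponsibilityState = None
    sticks: StickPosterior = None
    blocks: list = None
    trunc: TruncationConfig = None
    prior: PriorConfig = None

    @property
    def n_effective_views(self):
        return len(self.effective_views)

    @property
    def final_elbo(self):
        return float(self.elbo_traces[self.best_restart][-1])


# ---------------------------------------------------------------------------
# shared internals
# ---------------------------------------------------------------------------

class _Prep:
    """Per-slab precomputation: family model and flattened suffstats."""

    def __init__(self, slab: FamilySlab):
        self.slab = slab
        self.model = family_model(slab.family, slab.n_levels)
        S = self.model.suffstats(slab.X, slab.mask)  # (n, d, P)
        self.P = S.shape[-1]
        self.S2 = np.ascontiguousarray(S.reshape(slab.n, slab.d * self.P))


def _prepare(bundle: DatasetBundle):
    bundle.validate_cells()
    return [_Prep(slab) for slab in bundle.slabs]


def _eta_weighted_suffstats(prep: _Prep, eta):
    """W[v, j, (k, p)] = sum_i eta[i,v,k] S[i,j,p].

    Laid out view-major with the (k, p) axes flattened last so that every
    contraction below is a plain BLAS matmul.
    """
    n, V, K = eta.shape
    d, P = prep.slab.d, prep.P
    W2 = eta.reshape(n, V * K).T @ prep.S2                  # (V*K, d*P)
    return np.ascontiguousarray(
        W2.reshape(V, K, d, P).transpose(0, 2, 1, 3)        # (V, d, K, P)
    ).reshape(V, d, K * P)


def _block_stats(prep: _Prep, tau_m, W, K):
    """T[v,g,k,p] = sum_j tau[j,g,v] W[v,j,(k,p)]: weighted block statistics."""
    V, G = W.shape[0], tau_m.shape[1]
    T = np.matmul(tau_m.transpose(2, 1, 0), W)              # (V, G, K*P)
    return T.reshape(V, G, K, prep.P)


def _weighted_stats(prep: _Prep, tau_m, eta):
    W = _eta_weighted_suffstats(prep, eta)
    return W, _block_stats(prep, tau_m, W, eta.shape[2])


def _exclusive_cumsum(x, axis):
    c = np.cumsum(x, axis=axis)
    return c - x


def _reverse_exclusive_cumsum(x, axis):
    return x.sum(axis=axis, keepdims=True) - np.cumsum(x, axis=axis)


def _stick_scores(gammas, axis):
    """E_q[log pi_c] for a truncated stick along ``axis`` of the components.

    ``gammas[..., 0/1]`` are the Beta parameters.  The score of component c
    is psi(g1_c) - psi(g1_c + g2_c) plus the accumulated log-(1-w) terms of
    the components before it.
    """
    g1, g2 = gammas[..., 0], gammas[..., 1]
    e_log_w = _psi(g1) - _psi(g1 + g2)
    e_log_1mw = _psi(g2) - _psi(g1 + g2)
    return e_log_w + _exclusive_cumsum(e_log_1mw, axis)


def _stick_gammas_from_mass(mass, concentration, axis):
    """Beta parameters (1 + mass_c, conc + mass beyond c) along ``axis``."""
    g1 = 1.0 + mass
    g2 = concentration + _reverse_exclusive_cumsum(mass, axis)
    return np.stack([g1, g2], axis=-1)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def init_responsibilities(bundle: DatasetBundle, trunc: TruncationConfig,
                          rng: np.random.Generator) -> ResponsibilityState:
    """Random start: near-hard assignments from sparse symmetric Dirichlets.

    Rows are drawn from Dirichlet(1/(G*V)) for features and Dirichlet(1/K)
    for objects, i.e. close to random hard assignments.  Diffuse (flat
    Dirichlet) starts collapse distinct views onto each other in the first
    sweeps and systematically land in poorer optima; near-hard starts
    explore the assignment space far better and reach markedly higher
    ELBOs under identical restart budgets.
    """
    V, G, K = trunc.V, trunc.G, trunc.K
    tau = []
    for slab in bundle.slabs:
        t = rng.dirichlet(np.full(G * V, 1.0 / (G * V)), size=slab.d)
        tau.append(t.reshape(slab.d, G, V))
    eta = rng.dirichlet(np.full(K, 1.0 / K), size=bundle.n * V).reshape(bundle.n, V, K)
    return ResponsibilityState(tau, eta)


def update_stick_posteriors(resp: ResponsibilityState, prior: PriorConfig) -> StickPosterior:
    """Closed-form Beta updates from the current responsibility masses."""
    view_mass = sum(t.sum(axis=(0, 1)) for t in resp.tau)        # (V,)
    view = _stick_gammas_from_mass(view_mass, prior.alpha1, axis=0)
    feat = []
    for t in resp.tau:
        fm = t.sum(axis=0)                                        # (G, V)
        feat.append(_stick_gammas_from_mass(fm, prior.alpha2, axis=0))
    om = resp.eta.sum(axis=0)                                     # (V, K)
    obj = _stick_gammas_from_mass(om, prior.beta_obj, axis=1)
    return StickPosterior(view, feat, obj)


def update_blocks(bundle: DatasetBundle, resp: ResponsibilityState,
                  prior: PriorConfig) -> list:
    """Conjugate posterior update of every (family, v, g, k) block."""
    preps = _prepare(bundle)
    return _update_blocks_prepared(preps, resp.tau, resp.eta, prior)


def _update_blocks_prepared(preps, tau, eta, prior):
    blocks = []
    for prep, tau_m in zip(preps, tau):
        _, T = _weighted_stats(prep, tau_m, eta)
        params = prep.model.update(T, prior)
        blocks.append(BlockPosterior(prep.slab.family, params, prep.slab.n_levels))
    return blocks


def _coefs(preps, blocks):
    return [prep.model.ell_coefs(bp.params) for prep, bp in zip(preps, blocks)]


def _tau_scores(prep, C, W, view_score, feat_score):
    """Unnormalized log responsibilities of features over (g, v)."""
    V, G, K, P = C.shape
    C2 = C.reshape(V, G, K * P)
    data = np.matmul(W, C2.transpose(0, 2, 1))                    # (V, d, G)
    return (
        data.transpose(1, 2, 0)
        + view_score[None, None, :]
        + feat_score[None, :, :]
    )


def _normalize_logits(flat):
    """Row-wise softmax in log space with a hard underflow floor."""
    mx = flat.max(axis=-1, keepdims=True)
    shifted = flat - mx
    np.maximum(shifted, _LOG_FLOOR, out=shifted)
    p = np.exp(shifted)
    p /= p.sum(axis=-1, keepdims=True)
    return p


def _normalize_tau(scores, family):
    d, G, V = scores.shape
    flat = scores.reshape(d, G * V)
    mx = flat.max(axis=1)
    if not np.all(np.isfinite(mx)):
        bad = int(np.argmin(np.isfinite(mx)))
        raise ValueError(
            f"all responsibility scores are -inf for {family} column {bad} "
            "(fully missing column with degenerate priors?)"
        )
    return _normalize_logits(flat).reshape(d, G, V)


def update_tau(bundle: DatasetBundle, eta: np.ndarray, sticks: StickPosterior,
               blocks: list) -> list:
    """Feature responsibility update, normalized over (g, v) per column."""
    preps = _prepare(bundle)
    tau = []
    view_score = _stick_scores(sticks.view, axis=0)
    for m, (prep, bp) in enumerate(zip(preps, blocks)):
        C = prep.model.ell_coefs(bp.params)
        W = _eta_weighted_suffstats(prep, eta)
        feat_score = _stick_scores(sticks.feat[m], axis=0)
        scores = _tau_scores(prep, C, W, view_score, feat_score)
        tau.append(_normalize_tau(scores, prep.slab.family))
    return tau


def _eta_scores(preps, Cs, tau, obj_score, n, V, K):
    data = np.zeros((n, V * K))
    for prep, C, tau_m in zip(preps, Cs, tau):
        d, P = prep.slab.d, prep.P
        C2 = C.reshape(V, -1, K * P)
        # F[j,p,v,k] = sum_g tau[j,g,v] C[v,g,k,p]: per-cell block-coefficient mix
        F = np.matmul(tau_m.transpose(2, 0, 1), C2)               # (V, d, K*P)
        F = np.ascontiguousarray(
            F.reshape(V, d, K, P).transpose(1, 3, 0, 2)           # (d, P, V, K)
        )
        data += prep.S2 @ F.reshape(d * P, V * K)
    return data.reshape(n, V, K) + obj_score[None, :, :]


def _normalize_eta(scores):
    n, V, K = scores.shape
    return _normalize_logits(scores.reshape(n * V, K)).reshape(n, V, K)


def update_eta(bundle: DatasetBundle, tau: list, sticks: StickPosterior,
               blocks: list) -> np.ndarray:
    """Object responsibility update, normalized over k per (object, view)."""
    preps = _prepare(bundle)
    Cs = _coefs(preps, blocks)
    V, K = sticks.obj.shape[0], sticks.obj.shape[1]
    obj_score = _stick_scores(sticks.obj, axis=1)
    scores = _eta_scores(preps, Cs, tau, obj_score, bundle.n, V, K)
    return _normalize_eta(scores)


def _xlogx(p):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)
    return out


def _elbo_terms(preps, tau, eta, sticks, blocks, prior, Ts=None):
    """All ELBO components; raises if any is non-finite."""
    if Ts is None:
        Ts = [_weighted_stats(prep, tau_m, eta)[1] for prep, tau_m in zip(preps, tau)]
    loglik = 0.0
    kl_blocks = 0.0
    for prep, bp, T in zip(preps, blocks, Ts):
        C = prep.model.ell_coefs(bp.params)
        loglik += float((C * T).sum())
        kl_blocks += prep.model.kl(bp.params, prior)

    view_score = _stick_scores(sticks.view, axis=0)
    y_term = 0.0
    for m, tau_m in enumerate(tau):
        feat_score = _stick_scores(sticks.feat[m], axis=0)
        prior_w = view_score[None, None, :] + feat_score[None, :, :]
        y_term += float((tau_m * prior_w).sum() - _xlogx(tau_m).sum())

    obj_score = _stick_scores(sticks.obj, axis=1)
    z_term = float((eta * obj_score[None, :, :]).sum() - _xlogx(eta).sum())

    kl_sticks = float(kl_beta(sticks.view[..., 0], sticks.view[..., 1], 1.0, prior.alpha1).sum())
    for f in sticks.feat:
        kl_sticks += float(kl_beta(f[..., 0], f[..., 1], 1.0, prior.alpha2).sum())
    kl_sticks += float(kl_beta(sticks.obj[..., 0], sticks.obj[..., 1], 1.0, prior.beta_obj).sum())

    parts = {
        "expected_loglik": loglik,
        "responsibility_Y": y_term,
        "responsibility_Z": z_term,
        "kl_sticks": -kl_sticks,
        "kl_blocks": -kl_blocks,
    }
    for name, value in parts.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite ELBO component: {name}")
    return parts


def compute_elbo(bundle: DatasetBundle, resp: ResponsibilityState,
                 sticks: StickPosterior, blocks: list, prior: PriorConfig) -> float:
    """Evidence lower bound of the current variational state (closed form)."""
    preps = _prepare(bundle)
    parts = _elbo_terms(preps, resp.tau, resp.eta, sticks, blocks, prior)
    return float(sum(parts.values()))


def preset_mode(mode: str, trunc: TruncationConfig, d_total: int = None) -> TruncationConfig:
    """Special-case model presets obtained by pinning truncation levels.

    ``cocluster`` (V=1) reduces the model to plain co-clustering;
    ``restricted_multiple`` (G=1) gives one feature cluster per view;
    ``independent_mixture`` (V=1, G=d) allows each feature its own cluster.
    """
    if mode == "multiple_cocluster":
        return trunc
    if mode == "cocluster":
        return replace(trunc, V=1)
    if mode == "restricted_multiple":
        return replace(trunc, G=1)
    if mode == "independent_mixture":
        if d_total is None:
            raise ValueError("independent_mixture preset requires d_total")
        return replace(trunc, V=1, G=d_total)
    raise ValueError(
        f"unknown mode {mode!r}; expected multiple_cocluster | cocluster | "
        "restricted_multiple | independent_mixture"
    )


# ---------------------------------------------------------------------------
# the fit loop
# ---------------------------------------------------------------------------

def _run_single(bundle, preps, trunc, prior, rng):
    """One restart of the coordinate-ascent loop.

    The ELBO of the state reached after sweep t is computed at the start of
    sweep t+1, reusing the weighted-statistic tensors that sweep needs
    anyway; convergence triggers on the relative change of consecutive
    entries.
    """
    resp = init_responsibilities(bundle, trunc, rng)
    tau, eta = resp.tau, resp.eta
    n, V, K = bundle.n, trunc.V, trunc.K

    blocks = None
    Cs = None
    sticks = None
    trace = []
    converged = False

    for _ in range(trunc.max_iter):
        WTs = [_weighted_stats(prep, tau_m, eta) for prep, tau_m in zip(preps, tau)]

        if blocks is not None:
            parts = _elbo_terms(preps, tau, eta, sticks, blocks, prior,
                                Ts=[T for _, T in WTs])
            elbo = sum(parts.values())
            if trace:
                prev = trace[-1]
                if abs(elbo - prev) <= trunc.elbo_tol * max(abs(prev), 1.0):
                    trace.append(elbo)
                    converged = True
                    break
            trace.append(elbo)

        blocks = []
        for prep, (_, T) in zip(preps, WTs):
            params = prep.model.update(T, prior)
            blocks.append(BlockPosterior(prep.slab.family, params, prep.slab.n_levels))
        Cs = _coefs(preps, blocks)

        sticks = update_stick_posteriors(ResponsibilityState(tau, eta), prior)
        view_score = _stick_scores(sticks.view, axis=0)
        feat_scores = [_stick_scores(f, axis=0) for f in sticks.feat]
        obj_score = _stick_scores(sticks.obj, axis=1)

        tau = [
            _normalize_tau(
                _tau_scores(prep, C, W, view_score, feat_scores[m]),
                prep.slab.family,
            )
            for m, (prep, C, (W, _)) in enumerate(zip(preps, Cs, WTs))
        ]
        eta = _normalize_eta(_eta_scores(preps, Cs, tau, obj_score, n, V, K))
    else:
        # max_iter exhausted: score the final state
        parts = _elbo_terms(preps, tau, eta, sticks, blocks, prior)
        trace.append(sum(parts.values()))

    return ResponsibilityState(tau, eta), sticks, blocks, np.asarray(trace), converged


def _map_assignments(resp: ResponsibilityState):
    map_view, map_g = [], []
    for t in resp.tau:
        d, G, V = t.shape
        idx = np.argmax(t.reshape(d, G * V), axis=1)
        map_g.append(idx // V)
        map_view.append(idx % V)
    map_Z = np.argmax(resp.eta, axis=2)
    return map_view, map_g, map_Z


def fit(bundle: DatasetBundle, trunc: TruncationConfig = None,
        prior: PriorConfig = None) -> FitResult:
    """Variational Bayes EM with random restarts; keeps the best ELBO run."""
    trunc = trunc or TruncationConfig()
    prior = prior or PriorConfig()
    preps = _prepare(bundle)

    best = None
    traces, converged_flags = [], []
    for s in range(trunc.n_restarts):
        rng = np.random.default_rng([trunc.seed, s])
        resp, sticks, blocks, trace, conv = _run_single(bundle, preps, trunc, prior, rng)
        traces.append(trace)
        converged_flags.append(conv)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], s, resp, sticks, blocks)

    _, s_star, resp, sticks, blocks = best
    map_view, map_g, map_Z = _map_assignments(resp)

    assigned = np.zeros(trunc.V, dtype=bool)
    for mv in map_view:
        assigned[np.unique(mv)] = True
    effective = np.flatnonzero(assigned)
    n_clusters = np.array([len(np.unique(map_Z[:, v])) for v in range(trunc.V)])

    return FitResult(
        map_view=map_view,
        map_feature_cluster=map_g,
        map_Z=map_Z,
        elbo_traces=traces,
        best_restart=s_star,
        effective_views=effective,
        n_object_clusters=n_clusters,
        converged=converged_flags,
        responsibilities=resp,
        sticks=sticks,
        blocks=blocks,
        trunc=trunc,
        prior=prior,
    )


def sweep_operation_count(bundle: DatasetBundle, trunc: TruncationConfig) -> int:
    """Number of multiply-add operations in the dominant per-sweep tensors.

    Used to verify the linear scaling of per-sweep cost in both n and the
    number of features at fixed truncation levels.
    """
    V, G, K = trunc.V, trunc.G, trunc.K
    total = 0
    for slab in bundle.slabs:
        P = slab.n_levels if slab.family == "categorical" else 3
        d, n = slab.d, slab.n
        total += n * V * K * d * P          # weighted statistics W
        total += V * G * K * d * P          # block statistics T
        total += V * G * K * d * P          # tau data scores
        total += d * G * V * K * P          # eta mixing tensor F
        total += n * d * P * V * K          # eta data scores
    return total
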