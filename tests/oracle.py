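"""Independent scalar (non-vectorized) reference implementations.

Everything here is written with explicit Python loops directly from the
coordinate-update formulas and the scalar per-block API, deliberately
avoiding the vectorised code paths of the package, so the two can be
compared as implementation vs oracle.
"""

import numpy as np
from scipy import special

from mvcoclust.observation import (
    PriorConfig,
    block_weight,
    expected_loglik,
    kl_beta,
    kl_dirichlet,
    kl_gamma,
    kl_normal_gamma,
    update_categorical_block,
    update_gaussian_block,
    update_poisson_block,
)

_UPDATERS = {
    "gaussian": update_gaussian_block,
    "poisson": update_poisson_block,
    "categorical": update_categorical_block,
}


def naive_blocks(bundle, tau, eta, prior: PriorConfig):
    """Per-block conjugate updates through the scalar API, block by block."""
    V, K = eta.shape[1], eta.shape[2]
    out = []
    for slab, tau_m in zip(bundle.slabs, tau):
        G = tau_m.shape[1]
        table = {}
        for v in range(V):
            for g in range(G):
                for k in range(K):
                    w = block_weight(tau_m[:, g, v], eta[:, v, k], slab.mask, slab.family)
                    if slab.family == "categorical":
                        table[v, g, k] = update_categorical_block(
                            slab.X, w, prior, slab.n_levels)
                    else:
                        table[v, g, k] = _UPDATERS[slab.family](slab.X, w, prior)
        out.append(table)
    return out


def _stick_gammas(masses, conc):
    """[(g1_c, g2_c)] for one truncated stick from component masses."""
    total = sum(masses)
    acc = 0.0
    out = []
    for c, mass in enumerate(masses):
        out.append((1.0 + mass, conc + (total - acc - mass)))
        acc += mass
    return out


def naive_sticks(tau, eta, prior: PriorConfig):
    V, K = eta.shape[1], eta.shape[2]
    view_mass = [sum(t[:, :, v].sum() for t in tau) for v in range(V)]
    view = _stick_gammas(view_mass, prior.alpha1)
    feat = []
    for t in tau:
        G = t.shape[1]
        feat.append([_stick_gammas([t[:, g, v].sum() for g in range(G)], prior.alpha2)
                     for v in range(V)])  # feat[m][v][g]
    obj = [_stick_gammas([eta[:, v, k].sum() for k in range(K)], prior.beta_obj)
           for v in range(V)]  # obj[v][k]
    return view, feat, obj


def _stick_score(gammas, c):
    """E[log pi_c] from a list of per-component (g1, g2) pairs."""
    psi = special.digamma
    g1, g2 = gammas[c]
    score = psi(g1) - psi(g1 + g2)
    for t in range(c):
        a, b = gammas[t]
        score += psi(b) - psi(a + b)
    return score


def naive_tau(bundle, eta, view, feat, blocks):
    """Feature responsibility update, Eq-by-Eq with explicit loops."""
    V, K = eta.shape[1], eta.shape[2]
    tau = []
    for m, (slab, table) in enumerate(zip(bundle.slabs, blocks)):
        G = max(g for _, g, _ in table) + 1
        t_out = np.zeros((slab.d, G, V))
        for j in range(slab.d):
            scores = np.zeros((G, V))
            for v in range(V):
                for g in range(G):
                    s = _stick_score(view, v) + _stick_score(feat[m][v], g)
                    for k in range(K):
                        for i in range(slab.n):
                            if slab.mask[i, j]:
                                s += eta[i, v, k] * expected_loglik(
                                    slab.family, slab.X[i, j], table[v, g, k])
                    scores[g, v] = s
            ex = np.exp(scores - scores.max())
            t_out[j] = ex / ex.sum()
        tau.append(t_out)
    return tau


def naive_eta(bundle, tau, obj, blocks):
    n = bundle.n
    V = tau[0].shape[2]
    K = len(obj[0])
    out = np.zeros((n, V, K))
    for i in range(n):
        for v in range(V):
            scores = np.zeros(K)
            for k in range(K):
                s = _stick_score(obj[v], k)
                for slab, tau_m, table in zip(bundle.slabs, tau, blocks):
                    G = tau_m.shape[1]
                    for g in range(G):
                        for j in range(slab.d):
                            if slab.mask[i, j]:
                                s += tau_m[j, g, v] * expected_loglik(
                                    slab.family, slab.X[i, j], table[v, g, k])
                scores[k] = s
            ex = np.exp(scores - scores.max())
            out[i, v] = ex / ex.sum()
    return out


def naive_elbo(bundle, tau, eta, view, feat, obj, blocks, prior: PriorConfig):
    """ELBO assembled term by term with loops and the scalar block API."""
    V, K = eta.shape[1], eta.shape[2]
    total = 0.0
    # expected complete-data log-likelihood over observed cells
    for slab, tau_m, table in zip(bundle.slabs, tau, blocks):
        G = tau_m.shape[1]
        for v in range(V):
            for g in range(G):
                for k in range(K):
                    for j in range(slab.d):
                        for i in range(slab.n):
                            if slab.mask[i, j]:
                                total += tau_m[j, g, v] * eta[i, v, k] * expected_loglik(
                                    slab.family, slab.X[i, j], table[v, g, k])
    # responsibilities vs their stick-implied priors
    for m, tau_m in enumerate(tau):
        d, G, _ = tau_m.shape
        for j in range(d):
            for v in range(V):
                for g in range(G):
                    p = tau_m[j, g, v]
                    if p > 0:
                        total += p * (_stick_score(view, v)
                                      + _stick_score(feat[m][v], g) - np.log(p))
    for i in range(bundle.n):
        for v in range(V):
            for k in range(K):
                p = eta[i, v, k]
                if p > 0:
                    total += p * (_stick_score(obj[v], k) - np.log(p))
    # stick KL terms
    for g1, g2 in view:
        total -= kl_beta(g1, g2, 1.0, prior.alpha1)
    for fm in feat:
        for per_view in fm:
            for g1, g2 in per_view:
                total -= kl_beta(g1, g2, 1.0, prior.alpha2)
    for per_view in obj:
        for g1, g2 in per_view:
            total -= kl_beta(g1, g2, 1.0, prior.beta_obj)
    # block KL terms
    for slab, table in zip(bundle.slabs, blocks):
        for blk in table.values():
            if slab.family == "gaussian":
                total -= kl_normal_gamma(
                    blk.m, blk.beta, blk.a, blk.b,
                    prior.gaussian_m0, prior.gaussian_beta0,
                    prior.gaussian_a0, prior.gaussian_b0)
            elif slab.family == "poisson":
                total -= kl_gamma(blk.a, blk.b, prior.poisson_a0, prior.poisson_b0)
            else:
                total -= kl_dirichlet(blk.alpha, prior.dirichlet_alpha0)
    return float(total)


# ---------------------------------------------------------------------------
# exact marginal likelihood by enumeration (tiny instances only)
# ---------------------------------------------------------------------------

def _log_block_marginal(family, x, prior: PriorConfig, n_levels=None):
    """Closed-form log marginal likelihood of the cells in one block."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return 0.0
    if family == "gaussian":
        blk = update_gaussian_block(x, np.ones(n), prior)
        return float(
            special.gammaln(blk.a) - special.gammaln(prior.gaussian_a0)
            + prior.gaussian_a0 * np.log(prior.gaussian_b0) - blk.a * np.log(blk.b)
            + 0.5 * (np.log(prior.gaussian_beta0) - np.log(blk.beta))
            - 0.5 * n * np.log(2 * np.pi)
        )
    if family == "poisson":
        blk = update_poisson_block(x, np.ones(n), prior)
        return float(
            special.gammaln(blk.a) - special.gammaln(prior.poisson_a0)
            + prior.poisson_a0 * np.log(prior.poisson_b0) - blk.a * np.log(blk.b)
            - special.gammaln(x + 1.0).sum()
        )
    if family == "categorical":
        counts = np.bincount(x.astype(int), minlength=n_levels)
        a0 = np.full(n_levels, prior.dirichlet_alpha0)
        return float(
            special.gammaln(a0.sum()) - special.gammaln(a0.sum() + n)
            + (special.gammaln(a0 + counts) - special.gammaln(a0)).sum()
        )
    raise ValueError(family)


def _log_stick_assignment_prob(counts, conc):
    """log E[prod_c pi_c^{n_c}] for one truncated stick, via Beta moments."""
    total = 0.0
    beyond = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    for c, n_c in enumerate(counts):
        total += special.betaln(1.0 + n_c, conc + beyond[c]) - special.betaln(1.0, conc)
    return float(total)


def exact_log_marginal(bundle, V, G, K, prior: PriorConfig):
    """log p(X) with assignments restricted to the (V, G, K) truncation.

    Enumerates every feature-to-(g, v) and object-to-cluster assignment,
    scoring each with exact stick-prior probabilities (Beta moments) and
    closed-form conjugate block marginals.  A partial sum of the full
    nonparametric marginal, hence a certified upper bound on the ELBO of
    any variational state supported on the same truncation.
    """
    from itertools import product

    n = bundle.n
    d_all = [slab.d for slab in bundle.slabs]
    log_terms = []
    y_choices = [list(product(range(G * V), repeat=d)) for d in d_all]
    for y_flat in product(*y_choices):
        # per-family feature assignments: flat index = g * V + v
        y = [np.array([(f // V, f % V) for f in yf], dtype=int).reshape(-1, 2)
             if len(yf) else np.zeros((0, 2), int) for yf in y_flat]
        log_py = 0.0
        view_counts = np.zeros(V)
        for ym in y:
            for g, v in ym:
                view_counts[v] += 1
        log_py += _log_stick_assignment_prob(view_counts, prior.alpha1)
        for ym in y:
            for v in range(V):
                g_counts = np.zeros(G)
                for g, vv in ym:
                    if vv == v:
                        g_counts[g] += 1
                log_py += _log_stick_assignment_prob(g_counts, prior.alpha2)
        for z_flat in product(range(K), repeat=n * V):
            z = np.array(z_flat).reshape(n, V)
            log_pz = 0.0
            for v in range(V):
                k_counts = np.bincount(z[:, v], minlength=K).astype(float)
                log_pz += _log_stick_assignment_prob(k_counts, prior.beta_obj)
            log_lik = 0.0
            for slab, ym in zip(bundle.slabs, y):
                for v in range(V):
                    for g in range(G):
                        cols = [j for j in range(slab.d)
                                if ym[j, 0] == g and ym[j, 1] == v]
                        if not cols:
                            continue
                        for k in range(K):
                            cells = [slab.X[i, j] for j in cols for i in range(n)
                                     if slab.mask[i, j] and z[i, v] == k]
                            log_lik += _log_block_marginal(
                                slab.family, np.array(cells), prior, slab.n_levels)
            log_terms.append(log_py + log_pz + log_lik)
    return float(special.logsumexp(np.array(log_terms)))
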