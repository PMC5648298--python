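"""Conjugate univariate block observation models.

Every cluster block -- the intersection of one feature cluster and one
object cluster inside a view -- is modelled by a single univariate
distribution with a conjugate prior:

* Gaussian features: Normal-Gamma prior on (mean, precision),
* Poisson counts: Gamma prior on the rate,
* categorical levels: symmetric Dirichlet prior on the level probabilities.

The variational algorithm only ever needs two things from a block model:

1. a posterior update driven by *weighted* sufficient statistics, where the
   weight of a data cell is the product of its feature responsibility, its
   object responsibility, and its observed-entry indicator; and
2. the expectation of the log density of a cell under the current block
   posterior.

Both are provided here in two flavours: a scalar per-block API
(:func:`update_gaussian_block` and friends) used as the readable reference,
and vectorised family models (:class:`GaussianModel`, ...) that operate on
``(V, G, K)`` stacks of blocks at once and are used by the inference loop.
The two are required (and tested) to agree exactly.

Missing cells never reach these functions: their weight is zero, which by
construction makes them contribute nothing to any sufficient statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np
from scipy import special

_PSI_FLOOR = 1e-12
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

FAMILIES = ("gaussian", "poisson", "categorical")


def _psi(x):
    """Digamma with the arguments floored at a tiny positive value."""
    return special.digamma(np.maximum(x, _PSI_FLOOR))


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of all conjugate priors and stick concentrations.

    Defaults are weakly informative and assume Gaussian features are
    standardized before fitting.  ``alpha1``/``alpha2`` are the Beta
    concentrations of the view and feature-cluster sticks, ``beta_obj``
    that of the object-cluster sticks; all default to one.
    """

    gaussian_m0: float = 0.0
    gaussian_beta0: float = 1.0
    gaussian_a0: float = 1.0
    gaussian_b0: float = 1.0
    poisson_a0: float = 1.0
    poisson_b0: float = 1.0
    dirichlet_alpha0: float = 1.0
    alpha1: float = 1.0
    alpha2: float = 1.0
    beta_obj: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            if f.name == "gaussian_m0":  # a location, may be any real
                continue
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"PriorConfig.{f.name} must be > 0, got {value!r}")


class GaussianBlock(NamedTuple):
    m: float
    beta: float
    a: float
    b: float


class PoissonBlock(NamedTuple):
    a: float
    b: float


class CategoricalBlock(NamedTuple):
    alpha: np.ndarray  # (L,) Dirichlet counts


# ---------------------------------------------------------------------------
# scalar per-block API
# ---------------------------------------------------------------------------

def block_weight(tau_col, eta_col, mask, family: str = "") -> np.ndarray:
    """Per-cell weights ``w[i, j] = eta[i] * tau[j] * mask[i, j]``.

    ``tau_col`` is the responsibility of each feature for the block's
    (feature-cluster, view) pair, ``eta_col`` the responsibility of each
    object for the block's object cluster, and ``mask`` the observed-entry
    indicator of the data slab.
    """
    tau_col = np.asarray(tau_col, dtype=float)
    eta_col = np.asarray(eta_col, dtype=float)
    mask = np.asarray(mask)
    expected = (eta_col.shape[0], tau_col.shape[0])
    if mask.shape != expected:
        raise ValueError(
            f"mask shape {mask.shape} does not match the "
            f"{family or 'data'} slab dimensions {expected}"
        )
    if tau_col.min(initial=0.0) < 0 or tau_col.max(initial=0.0) > 1:
        raise ValueError("tau responsibilities must lie in [0, 1]")
    if eta_col.min(initial=0.0) < 0 or eta_col.max(initial=0.0) > 1:
        raise ValueError("eta responsibilities must lie in [0, 1]")
    return eta_col[:, None] * tau_col[None, :] * mask


def _weighted_moments(x, weights):
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError(f"data shape {x.shape} != weight shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("negative cell weight")
    observed = w > 0
    if not np.all(np.isfinite(x[observed])):
        raise ValueError("non-finite value in an observed (weighted) cell")
    xf = np.where(observed, x, 0.0)
    return xf, w, float(w.sum())


def update_gaussian_block(x, weights, prior: PriorConfig) -> GaussianBlock:
    """Normal-Gamma posterior from fractionally weighted observations."""
    xf, w, n_eff = _weighted_moments(x, weights)
    m0, b0 = prior.gaussian_m0, prior.gaussian_beta0
    if n_eff == 0.0:
        return GaussianBlock(m0, b0, prior.gaussian_a0, prior.gaussian_b0)
    xbar = float((w * xf).sum()) / n_eff
    scatter = float((w * (xf - xbar) ** 2).sum())
    m = (b0 * m0 + n_eff * xbar) / (b0 + n_eff)
    beta = b0 + n_eff
    a = prior.gaussian_a0 + n_eff / 2.0
    b = prior.gaussian_b0 + scatter / 2.0 + b0 * n_eff * (xbar - m0) ** 2 / (2.0 * (b0 + n_eff))
    return GaussianBlock(m, beta, a, b)


def update_poisson_block(x, weights, prior: PriorConfig) -> PoissonBlock:
    """Gamma posterior for the Poisson rate from weighted counts."""
    xf, w, n_eff = _weighted_moments(x, weights)
    obs = w > 0
    if np.any(xf[obs] < 0) or not np.allclose(xf[obs], np.rint(xf[obs])):
        raise ValueError("Poisson cells must be nonnegative integers")
    return PoissonBlock(prior.poisson_a0 + float((w * xf).sum()), prior.poisson_b0 + n_eff)


def update_categorical_block(x, weights, prior: PriorConfig, n_levels: int) -> CategoricalBlock:
    """Dirichlet posterior over a fixed level set from weighted cells.

    Levels are integer codes ``0..n_levels-1`` frozen from the full dataset;
    a code outside that support is an error even if the block never saw it.
    """
    xf, w, _ = _weighted_moments(x, weights)
    obs = w > 0
    codes = np.rint(xf[obs]).astype(int)
    if not np.allclose(xf[obs], codes):
        raise ValueError("categorical cells must be integer level codes")
    if codes.size and (codes.min() < 0 or codes.max() >= n_levels):
        raise ValueError(
            f"categorical level outside the declared support 0..{n_levels - 1}"
        )
    alpha = np.full(n_levels, prior.dirichlet_alpha0)
    np.add.at(alpha, codes, w[obs])
    return CategoricalBlock(alpha)


def expected_loglik(family: str, x, block) -> np.ndarray:
    """E_q[log p(x | theta)] of observed cell(s) under a block posterior."""
    x = np.asarray(x, dtype=float)
    if family == "gaussian":
        m, beta, a, b = block
        if not (a > 0 and b > 0 and beta > 0):
            raise ValueError("Gaussian block posterior parameters must be positive")
        return (
            0.5 * (_psi(a) - np.log(b))
            - _HALF_LOG_2PI
            - (a / (2.0 * b)) * (x - m) ** 2
            - 1.0 / (2.0 * beta)
        )
    if family == "poisson":
        a, b = block
        if not (a > 0 and b > 0):
            raise ValueError("Poisson block posterior parameters must be positive")
        return x * (_psi(a) - np.log(b)) - a / b - special.gammaln(x + 1.0)
    if family == "categorical":
        (alpha,) = block
        alpha = np.asarray(alpha, dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet counts must be positive")
        codes = np.rint(x).astype(int)
        return _psi(alpha)[codes] - _psi(alpha.sum())
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# KL divergences of the conjugate posteriors from their priors
# ---------------------------------------------------------------------------

def kl_beta(a1, b1, a0, b0):
    """KL( Beta(a1, b1) || Beta(a0, b0) ), elementwise."""
    return (
        special.betaln(a0, b0)
        - special.betaln(a1, b1)
        + (a1 - a0) * _psi(a1)
        + (b1 - b0) * _psi(b1)
        + (a0 + b0 - a1 - b1) * _psi(a1 + b1)
    )


def kl_gamma(a, b, a0, b0):
    """KL( Gamma(a, b) || Gamma(a0, b0) ), shape/rate parameterisation."""
    return (
        (a - a0) * _psi(a)
        - special.gammaln(a)
        + special.gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def kl_normal_gamma(m, beta, a, b, m0, beta0, a0, b0):
    """KL of a Normal-Gamma posterior from its prior, elementwise."""
    return kl_gamma(a, b, a0, b0) + 0.5 * (
        beta0 * (a / b) * (m - m0) ** 2 + beta0 / beta - 1.0 + np.log(beta / beta0)
    )


def kl_dirichlet(alpha, alpha0):
    """KL( Dir(alpha) || Dir(alpha0) ) along the last axis.

    ``alpha0`` may be a scalar (symmetric prior) broadcast to alpha's shape.
    """
    alpha = np.asarray(alpha, dtype=float)
    a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), alpha.shape)
    s = alpha.sum(axis=-1)
    s0 = a0.sum(axis=-1)
    return (
        special.gammaln(s)
        - special.gammaln(s0)
        - (special.gammaln(alpha) - special.gammaln(a0)).sum(axis=-1)
        + ((alpha - a0) * (_psi(alpha) - _psi(s)[..., None])).sum(axis=-1)
    )


# ---------------------------------------------------------------------------
# vectorised family models
# ---------------------------------------------------------------------------
#
# Each family exposes per-cell sufficient statistics S(x) of fixed width P
# and block coefficients C such that E_q[log p(x | theta_{v,g,k})] equals
# sum_p C[v,g,k,p] * S_p(x).  The same S vectors, accumulated with the
# tau*eta*mask weights, are exactly the weighted statistics the conjugate
# updates need -- one pass serves both purposes.

class GaussianModel:
    name = "gaussian"
    n_stats = 3  # (1, x, x^2)

    def suffstats(self, X, mask):
        Xf = np.where(mask, X, 0.0)
        S = np.empty(X.shape + (3,))
        S[..., 0] = 1.0
        S[..., 1] = Xf
        S[..., 2] = Xf * Xf
        S *= mask[..., None]
        return S

    def update(self, T, prior: PriorConfig):
        n_eff = np.maximum(T[..., 0], 0.0)
        sx, sxx = T[..., 1], T[..., 2]
        m0, b0 = prior.gaussian_m0, prior.gaussian_beta0
        nonempty = n_eff > 0
        xbar = np.where(nonempty, sx / np.maximum(n_eff, 1e-300), 0.0)
        scatter = np.maximum(sxx - n_eff * xbar**2, 0.0)
        m = (b0 * m0 + sx) / (b0 + n_eff)
        beta = b0 + n_eff
        a = prior.gaussian_a0 + n_eff / 2.0
        b = prior.gaussian_b0 + scatter / 2.0 + b0 * n_eff * (xbar - m0) ** 2 / (2.0 * (b0 + n_eff))
        return {"m": m, "beta": beta, "a": a, "b": b}

    def ell_coefs(self, params):
        m, beta, a, b = params["m"], params["beta"], params["a"], params["b"]
        r = a / b
        C = np.empty(m.shape + (3,))
        C[..., 0] = 0.5 * (_psi(a) - np.log(b)) - _HALF_LOG_2PI - 0.5 / beta - 0.5 * r * m**2
        C[..., 1] = r * m
        C[..., 2] = -0.5 * r
        return C

    def kl(self, params, prior: PriorConfig):
        return float(
            kl_normal_gamma(
                params["m"], params["beta"], params["a"], params["b"],
                prior.gaussian_m0, prior.gaussian_beta0,
                prior.gaussian_a0, prior.gaussian_b0,
            ).sum()
        )

    def block(self, params, v, g, k):
        return GaussianBlock(
            params["m"][v, g, k], params["beta"][v, g, k],
            params["a"][v, g, k], params["b"][v, g, k],
        )


class PoissonModel:
    name = "poisson"
    n_stats = 3  # (1, x, log x!)

    def suffstats(self, X, mask):
        Xf = np.where(mask, X, 0.0)
        S = np.empty(X.shape + (3,))
        S[..., 0] = 1.0
        S[..., 1] = Xf
        S[..., 2] = special.gammaln(Xf + 1.0)
        S *= mask[..., None]
        return S

    def update(self, T, prior: PriorConfig):
        n_eff = np.maximum(T[..., 0], 0.0)
        return {"a": prior.poisson_a0 + T[..., 1], "b": prior.poisson_b0 + n_eff}

    def ell_coefs(self, params):
        a, b = params["a"], params["b"]
        C = np.empty(a.shape + (3,))
        C[..., 0] = -a / b
        C[..., 1] = _psi(a) - np.log(b)
        C[..., 2] = -1.0
        return C

    def kl(self, params, prior: PriorConfig):
        return float(
            kl_gamma(params["a"], params["b"], prior.poisson_a0, prior.poisson_b0).sum()
        )

    def block(self, params, v, g, k):
        return PoissonBlock(params["a"][v, g, k], params["b"][v, g, k])


class CategoricalModel:
    name = "categorical"

    def __init__(self, n_levels: int):
        if n_levels < 2:
            raise ValueError("categorical family needs at least two levels")
        self.n_levels = n_levels
        self.n_stats = n_levels  # one-hot level indicators

    def suffstats(self, X, mask):
        codes = np.rint(np.where(mask, X, 0.0)).astype(int)
        S = np.zeros(X.shape + (self.n_levels,))
        n, d = X.shape
        S[np.arange(n)[:, None], np.arange(d)[None, :], codes] = 1.0
        S *= mask[..., None]
        return S

    def update(self, T, prior: PriorConfig):
        return {"alpha": prior.dirichlet_alpha0 + np.maximum(T, 0.0)}

    def ell_coefs(self, params):
        alpha = params["alpha"]
        return _psi(alpha) - _psi(alpha.sum(axis=-1))[..., None]

    def kl(self, params, prior: PriorConfig):
        return float(kl_dirichlet(params["alpha"], prior.dirichlet_alpha0).sum())

    def block(self, params, v, g, k):
        return CategoricalBlock(params["alpha"][v, g, k])


def family_model(family: str, n_levels: int | None = None):
    """Instantiate the vectorised model for one distribution family."""
    if family == "gaussian":
        return GaussianModel()
    if family == "poisson":
        return PoissonModel()
    if family == "categorical":
        if n_levels is None:
            raise ValueError("categorical family requires n_levels")
        return CategoricalModel(n_levels)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass
class BlockPosterior:
    """Stack of conjugate block posteriors for one distribution family.

    ``params`` holds one array per hyperparameter, each of shape
    ``(V, G, K)`` (``(V, G, K, L)`` for Dirichlet counts).  With zero
    responsibility mass in a block the entry equals the prior exactly.
    """

    family: str
    params: dict
    n_levels: int | None = None

    @property
    def shape(self):
        key = next(iter(self.params))
        return self.params[key].shape[:3]

    def block(self, v: int, g: int, k: int):
        """Scalar view of one block, for the per-block API."""
        model = family_model(self.family, self.n_levels)
        return model.block(self.params, v, g, k)
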