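"""Finite univariate Poisson mixtures fitted by EM, with BIC model choice.

Gene units (subject x tissue x gene) are grouped into "comparable" coverage
classes by fitting ``p(x) = sum_k pi_k Poisson(x; lambda_k)`` to the rounded
per-unit coverage averages.  Components are always reported in ascending
order of their means, so fits are invariant to initialisation permutations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "PoissonMixtureModel",
    "fit_poisson_mixture_em",
    "bic",
    "select_k_bic",
    "classify_units",
]

_MIN_RATE = 1e-6


@dataclasses.dataclass(frozen=True)
class PoissonMixtureModel:
    """Fitted mixture: weights ``pi`` and means ``lam`` sorted ascending."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    loglik: float
    bic: float
    n_obs: int
    converged: bool
    n_iter: int
    loglik_path: tuple = ()

    def __post_init__(self):
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-10:
            raise ValueError("mixture weights must sum to 1")


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, -2 log L + p ln n."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_obs) if n_params else -2.0 * loglik


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(np.int64)


def _init_means(
    values: np.ndarray, K: int, rng: np.random.Generator, perturb: bool,
    spread: bool = False,
):
    qs = (np.arange(K) + 0.5) / K
    if spread:
        # quantiles of the distinct values: spreads starting means across
        # the full range even when most mass sits in one narrow bulk
        lam = np.quantile(np.unique(values), qs)
    else:
        lam = np.quantile(values, qs)
    lam = np.maximum(lam, _MIN_RATE)
    if perturb:
        lam = lam * rng.uniform(0.6, 1.5, size=K)
    # distinct starting means
    lam = np.sort(lam)
    for i in range(1, K):
        if lam[i] <= lam[i - 1]:
            lam[i] = lam[i - 1] * 1.05 + 0.1
    return lam


def fit_poisson_mixture_em(
    values,
    K: int,
    init: str = "quantile",
    tol: float = 1e-7,
    max_iter: int = 500,
    seed=None,
    _perturb: bool = False,
    _spread_init: bool = False,
) -> PoissonMixtureModel:
    """Fit a K-component Poisson mixture by EM.

    ``values`` are coverage averages; they are rounded half-up to integers
    before likelihood evaluation.  The log-likelihood is non-decreasing
    across iterations; convergence is declared when the improvement falls
    below ``tol``.
    """
    vals = _round_half_up(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    uniq, counts = np.unique(vals, return_counts=True)
    if K > uniq.size:
        raise ValueError(f"K={K} exceeds the number of distinct values ({uniq.size})")
    n = int(vals.size)
    rng = np.random.default_rng(seed)

    if init != "quantile":
        raise ValueError(f"unknown init strategy {init!r}")
    lam = _init_means(vals, K, rng, _perturb, spread=_spread_init)
    pi = np.full(K, 1.0 / K)

    loglik = -np.inf
    converged = False
    it = 0
    path = []
    for it in range(1, max_iter + 1):
        log_comp = stats.poisson.logpmf(uniq[None, :], lam[:, None]) + np.log(pi)[:, None]
        log_norm = logsumexp(log_comp, axis=0)
        new_loglik = float(np.dot(counts, log_norm))
        path.append(new_loglik)
        resp = np.exp(log_comp - log_norm[None, :])  # (K, U)
        wk = resp * counts[None, :]
        nk = wk.sum(axis=1)
        pi = nk / n
        lam = np.maximum((wk @ uniq) / np.maximum(nk, 1e-300), _MIN_RATE)
        if new_loglik - loglik < tol * (1.0 + abs(new_loglik)) and np.isfinite(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    order = np.argsort(lam)
    lam, pi = lam[order], pi[order]
    pi = pi / pi.sum()
    log_comp = stats.poisson.logpmf(uniq[None, :], lam[:, None]) + np.log(pi)[:, None]
    loglik = float(np.dot(counts, logsumexp(log_comp, axis=0)))
    model_bic = bic(loglik, 2 * K - 1, n)
    return PoissonMixtureModel(
        K=K, weights=pi, means=lam, loglik=loglik, bic=model_bic,
        n_obs=n, converged=converged, n_iter=it, loglik_path=tuple(path),
    )


def select_k_bic(
    values,
    k_range,
    restarts: int = 3,
    seed=None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> PoissonMixtureModel:
    """Fit over ``k_range`` (iterable of K) and return the minimum-BIC model.

    Each K gets a deterministic quantile start plus ``restarts - 1``
    perturbed restarts; BIC ties resolve to the smaller K.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: PoissonMixtureModel | None = None
    uniq_count = np.unique(_round_half_up(np.asarray(values, dtype=float))).size
    for k in ks:
        if k > uniq_count:
            continue
        child_seeds = ss.spawn(max(restarts, 1))
        best_k: PoissonMixtureModel | None = None
        for r in range(max(restarts, 1)):
            fit = fit_poisson_mixture_em(
                values, k, tol=tol, max_iter=max_iter,
                seed=child_seeds[r], _perturb=(r > 1),
                _spread_init=(r % 2 == 1),
            )
            if best_k is None or fit.loglik > best_k.loglik:
                best_k = fit
        if best is None or best_k.bic < best.bic:
            best = best_k
    if best is None:
        raise ValueError("no K in k_range is feasible for these values")
    return best


def classify_units(model: PoissonMixtureModel, mean_totals):
    """Posterior component membership for unit coverage averages.

    Returns ``(labels, posteriors)`` where ``posteriors`` is (n, K) with
    rows summing to 1 and ``labels`` the argmax (ties to the lowest index,
    i.e. the smallest mean).
    """
    vals = _round_half_up(np.asarray(mean_totals, dtype=float))
    log_comp = (
        stats.poisson.logpmf(vals[None, :], model.means[:, None])
        + np.log(model.weights)[:, None]
    )
    log_norm = logsumexp(log_comp, axis=0)
    post = np.exp(log_comp - log_norm[None, :]).T
    labels = np.argmax(post, axis=1)
    return labels, post
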