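"""Folded Skellam mixtures: fitting, per-component testing and SNP calls.

Within one coverage-and-region stratum the absolute adjusted read
differences ``y = |R - V|`` are modelled as

    p(y) = sum_i pi_i * FoldedSkellam(y; lambda_i1, lambda_i2),

where a component with clearly unequal rates captures allelically
imbalanced SNPs and a near-equal-rates component captures balanced noise.
Because the fold destroys the sign, each rate pair is identifiable only up
to order; components store the larger rate first and are sorted by total
rate.  Each component is screened for imbalance with a likelihood-ratio
test of equal Poisson rates: the null rate comes from the method of moments
(E(R-V)^2 = 2*lambda) and the statistic is referred to chi-square(1).

The default fitting backend is EM with the exact pmf (the likelihood is
computable through Bessel functions); a likelihood-free MCMC backend lives
in :mod:`aeimix.abc_backend` and serves as a cross-check.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .skellam import (
    SkellamParams,
    chisq1_pvalue,
    folded_skellam_logpmf,
    folded_skellam_loglik,
    mom_lambda_null,
)

__all__ = [
    "FoldedSkellamComponent",
    "FoldedSkellamMixtureModel",
    "ComponentTestResult",
    "fit_mixture_em",
    "select_k_bic_folded",
    "posterior_probs",
    "lrt_equal_means",
    "designate_signal_components",
    "classify_snps",
]

_MIN_RATE = 1e-6


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclasses.dataclass(frozen=True)
class FoldedSkellamComponent:
    """One mixture component; ``lambda_hi >= lambda_lo`` by convention."""

    weight: float
    lambda_hi: float
    lambda_lo: float

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")
        if self.lambda_hi < 0 or self.lambda_lo < 0:
            raise ValueError("rates must be non-negative")
        if self.lambda_hi < self.lambda_lo:
            raise ValueError("store the larger rate first")

    @property
    def total(self) -> float:
        return self.lambda_hi + self.lambda_lo

    @property
    def gap(self) -> float:
        """|lambda1 - lambda2|, the location driver of the folded law."""
        return self.lambda_hi - self.lambda_lo

    @property
    def params(self) -> SkellamParams:
        return SkellamParams(self.lambda_hi, self.lambda_lo)


@dataclasses.dataclass(frozen=True)
class FoldedSkellamMixtureModel:
    K: int
    components: tuple
    loglik: float
    bic: float
    n_obs: int
    fit_method: str = "em_exact"
    converged: bool = True
    n_iter: int = 0
    diagnostics: dict | None = None

    def __post_init__(self):
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-10:
            raise ValueError("component weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def rate_pairs(self) -> np.ndarray:
        return np.array([(c.lambda_hi, c.lambda_lo) for c in self.components])


@dataclasses.dataclass
class ComponentTestResult:
    """LRT of equal Poisson rates for one component's assigned SNPs."""

    component: int
    n_assigned: int
    tested: bool
    L0: float = float("nan")
    L1: float = float("nan")
    stat: float = float("nan")
    pvalue: float = float("nan")
    lambda_null: float = float("nan")
    signal: bool = False


def _aggregate(abs_diffs) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(abs_diffs, dtype=np.int64)
    if y.size == 0:
        raise ValueError("abs_diffs must be non-empty")
    if np.any(y < 0):
        raise ValueError("absolute differences must be non-negative")
    return np.unique(y, return_counts=True)


def _log_matrix(uniq: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """(K, U) folded log pmf of each component at each unique value."""
    return np.vstack([folded_skellam_logpmf(uniq, (p[0], p[1])) for p in pairs])


def _weighted_negloglik(x: np.ndarray, uniq: np.ndarray, w: np.ndarray) -> float:
    lam = np.exp(x)
    lp = folded_skellam_logpmf(uniq, (lam[0], lam[1]))
    val = float(np.dot(w, lp))
    return -val if np.isfinite(val) else 1e300


def _maximize_component(uniq, w, lam_start, maxiter: int = 60) -> np.ndarray:
    """2-D maximization of the weighted folded-Skellam log-likelihood in
    log-rate coordinates (Nelder-Mead); never returns a worse point."""
    keep = w > 1e-10 * max(float(w.sum()), 1e-300)
    uniq, w = uniq[keep], w[keep]
    if uniq.size == 0:
        return np.asarray(lam_start, dtype=float)
    x0 = np.log(np.maximum(lam_start, _MIN_RATE))
    res = optimize.minimize(
        _weighted_negloglik, x0, args=(uniq, w), method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8},
    )
    if res.fun <= _weighted_negloglik(x0, uniq, w):
        return np.exp(res.x)
    return np.asarray(lam_start, dtype=float)


def _init_pairs(y: np.ndarray, K: int, rng: np.random.Generator, perturb: bool):
    """Quantile-block starts.

    Sorted values are split into K equal blocks; within a block the folded
    mean approximates the rate gap ``g = |l1 - l2|`` and, since
    ``E y^2 = (l1 + l2) + g^2`` for a folded Skellam, the total rate starts
    at ``mean(y^2) - g^2`` (floored).  Restarts jitter both moments.
    """
    ys = np.sort(y)
    blocks = np.array_split(ys, K)
    pairs = np.empty((K, 2))
    for i, b in enumerate(blocks):
        if b.size == 0:
            b = ys
        g = float(np.mean(b))
        t = float(np.mean(b.astype(float) ** 2) - g * g)
        t = max(t, g + 0.5, 1.0)
        if perturb:
            g *= rng.uniform(0.4, 1.8)
            t *= rng.uniform(0.4, 1.8)
            t = max(t, g + 0.5)
        pairs[i] = ((t + g) / 2.0, (t - g) / 2.0)
    return np.maximum(pairs, _MIN_RATE)


def _canonicalize(pi: np.ndarray, pairs: np.ndarray):
    pairs = np.sort(pairs, axis=1)[:, ::-1]  # hi first
    order = np.lexsort((pairs[:, 0] - pairs[:, 1], pairs.sum(axis=1)))
    return pi[order], pairs[order]


def fit_mixture_em(
    abs_diffs,
    K: int,
    init: str = "quantile",
    tol: float = 1e-7,
    max_iter: int = 300,
    seed=None,
    _perturb: bool = False,
    _state=None,
    _return_state: bool = False,
):
    """EM fit of a K-component folded Skellam mixture (exact pmf).

    E-step responsibilities are exact; the M-step re-optimises each
    component's rate pair by bounded 2-D numerical maximization warm-started
    at the current values, so the observed-data log-likelihood is
    non-decreasing.
    """
    uniq, counts = _aggregate(abs_diffs)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > uniq.size:
        raise ValueError(f"K={K} exceeds the number of distinct values ({uniq.size})")
    if init != "quantile":
        raise ValueError(f"unknown init strategy {init!r}")
    n = int(counts.sum())
    rng = np.random.default_rng(seed)
    y_full = np.repeat(uniq, counts)
    if _state is not None:
        pi, pairs = np.array(_state[0]), np.array(_state[1])
    else:
        pairs = _init_pairs(y_full, K, rng, _perturb)
        pi = np.full(K, 1.0 / K)

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = _log_matrix(uniq, pairs) + np.log(pi)[:, None]
        log_norm = logsumexp(log_comp, axis=0)
        new_loglik = float(np.dot(counts, log_norm))
        resp = np.exp(log_comp - log_norm[None, :])
        wk = resp * counts[None, :]
        nk = wk.sum(axis=1)
        pi = np.maximum(nk / n, 1e-12)
        pi = pi / pi.sum()
        # early iterations move parameters a lot; later ones only polish,
        # so the inner optimizer's budget shrinks after the first sweeps
        m_budget = 60 if it <= 8 else 30
        for i in range(K):
            if nk[i] <= 1e-8:
                continue
            pairs[i] = _maximize_component(uniq, wk[i], pairs[i], maxiter=m_budget)
        if np.isfinite(loglik) and new_loglik - loglik < tol * (1.0 + abs(new_loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    pi, pairs = _canonicalize(pi, pairs)
    log_comp = _log_matrix(uniq, pairs) + np.log(pi)[:, None]
    loglik = float(np.dot(counts, logsumexp(log_comp, axis=0)))
    from .poisson_mixture import bic as _bic

    comps = tuple(
        FoldedSkellamComponent(weight=float(p), lambda_hi=float(a), lambda_lo=float(b))
        for p, (a, b) in zip(pi, pairs)
    )
    model = FoldedSkellamMixtureModel(
        K=K, components=comps, loglik=loglik,
        bic=_bic(loglik, 3 * K - 1, n), n_obs=n,
        fit_method="em_exact", converged=converged, n_iter=it,
    )
    if _return_state:
        return model, (pi, pairs)
    return model


def fit_mixture_em_best(
    abs_diffs, K: int, restarts: int = 3, seed=None, tol: float = 1e-7,
    max_iter: int = 300,
) -> FoldedSkellamMixtureModel:
    """Multi-start EM: short runs from jittered starts, long run from the best.

    Each of the ``restarts`` starts (the first deterministic, the rest
    moment-jittered) runs a capped number of iterations; the most likely
    short run is then iterated to convergence.  This is the standard
    defence against the folded mixture's local optima.
    """
    ss = _seed_seq(seed)
    n_starts = max(restarts, 1)
    children = ss.spawn(n_starts)
    short_iter = min(40, max_iter)
    y = np.asarray(abs_diffs, dtype=np.int64)
    m2 = float(np.mean(y.astype(float) ** 2))
    best = None
    best_state = None
    for r in range(n_starts):
        state = None
        if r >= 2:
            # random start: gaps seeded by random data points, totals by a
            # jittered method-of-moments residual E y^2 - g^2
            rng = np.random.default_rng(children[r])
            g = np.sort(rng.choice(y, size=K).astype(float))
            t = np.maximum(m2 * rng.uniform(0.1, 2.0, K) - g * g, g + 1.0)
            prs = np.maximum(np.c_[(t + g) / 2.0, (t - g) / 2.0], _MIN_RATE)
            state = (np.full(K, 1.0 / K), prs)
        fit, state = fit_mixture_em(
            abs_diffs, K, tol=tol, max_iter=short_iter, seed=children[r],
            _perturb=(r == 1), _state=state, _return_state=True,
        )
        if best is None or fit.loglik > best.loglik:
            best, best_state = fit, state
    if best.converged:
        return best
    return fit_mixture_em(
        abs_diffs, K, tol=tol, max_iter=max_iter, _state=best_state
    )


def select_k_bic_folded(
    abs_diffs, k_range, restarts: int = 3, seed=None, tol: float = 1e-7,
    max_iter: int = 300,
) -> FoldedSkellamMixtureModel:
    """Minimum-BIC folded mixture over ``k_range``; ties go to smaller K."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    uniq, _ = _aggregate(abs_diffs)
    ss = _seed_seq(seed)
    children = ss.spawn(len(ks))
    best = None
    for k, child in zip(ks, children):
        if k > uniq.size:
            continue
        fit = fit_mixture_em_best(
            abs_diffs, k, restarts=restarts, seed=child, tol=tol, max_iter=max_iter
        )
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise ValueError("no K in k_range is feasible for these values")
    return best


def posterior_probs(model: FoldedSkellamMixtureModel, abs_diffs) -> np.ndarray:
    """(n, K) posterior component membership; rows sum to 1."""
    y = np.asarray(abs_diffs, dtype=np.int64)
    uniq, inverse = np.unique(y, return_inverse=True)
    log_comp = _log_matrix(uniq, model.rate_pairs) + np.log(model.weights)[:, None]
    log_norm = logsumexp(log_comp, axis=0)
    post_u = np.exp(log_comp - log_norm[None, :]).T
    return post_u[inverse]


def lrt_equal_means(
    model: FoldedSkellamMixtureModel,
    component: int,
    assigned_diffs,
    min_test_n: int = 10,
) -> ComponentTestResult:
    """Likelihood-ratio test of equal Poisson rates within one component.

    ``assigned_diffs`` are the absolute differences hard-assigned (argmax
    posterior) to the component.  The null log-likelihood L0 evaluates the
    equal-rates folded Skellam at the method-of-moments rate; L1 evaluates
    the component's fitted (unconstrained) rate pair from the overall
    mixture fit.  The statistic 2(L1 - L0) is clamped at zero and referred
    to chi-square(1); components with fewer than ``min_test_n`` points are
    not tested (reported as NA).
    """
    y = np.asarray(assigned_diffs, dtype=np.int64)
    n = int(y.size)
    if n < max(min_test_n, 1):
        return ComponentTestResult(component=component, n_assigned=n, tested=False)
    lam0 = mom_lambda_null(y)
    L0 = folded_skellam_loglik(y, (lam0, lam0))
    comp = model.components[component]
    L1 = folded_skellam_loglik(y, comp.params)
    stat = max(0.0, 2.0 * (L1 - L0))
    return ComponentTestResult(
        component=component, n_assigned=n, tested=True,
        L0=L0, L1=L1, stat=stat, pvalue=chisq1_pvalue(stat), lambda_null=lam0,
    )


def designate_signal_components(
    model: FoldedSkellamMixtureModel,
    results: Sequence[ComponentTestResult],
    alpha: float = 0.05,
    min_effect_sd: float = 1.0,
) -> set[int]:
    """Label components carrying allelic-imbalance signal.

    A tested component is a signal component when its LRT p-value is below
    ``alpha`` and its rate gap exceeds ``min_effect_sd`` standard
    deviations of its own count difference (sd = sqrt(lambda1 + lambda2)).
    The effect-size gate exists because component rate pairs are only
    set-identified along a gap/total ridge: a ridge excursion can
    manufacture a small spurious gap (bounded by about one sd) on a
    balanced component, while genuine imbalance sits several sd from
    parity.  Set ``min_effect_sd=0`` for the pure-LRT rule.  An untested
    (too small) component inherits the signal label when its rate gap
    exceeds the smallest gap among the designated components — it sits
    even further from zero than a component already shown to be
    imbalanced.
    """
    by_comp = {r.component: r for r in results}
    significant = {
        i for i, r in by_comp.items()
        if r.tested and r.pvalue < alpha
        and model.components[i].gap
        > min_effect_sd * np.sqrt(model.components[i].total)
    }
    signal = set(significant)
    if significant:
        min_sig_gap = min(model.components[i].gap for i in significant)
        for i, r in by_comp.items():
            if not r.tested and model.components[i].gap > min_sig_gap:
                signal.add(i)
    for r in results:
        r.signal = r.component in signal
    return signal


def classify_snps(
    model: FoldedSkellamMixtureModel,
    abs_diffs,
    signal_components: set[int],
    rule: str = "max_prob",
    threshold: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP posterior membership and imbalance designation.

    Under ``max_prob`` a SNP is called imbalanced when its argmax component
    is a signal component; under ``threshold`` when its aggregated signal
    probability (posterior mass on signal components) reaches ``threshold``.
    SNPs missing the call but with aggregated probability above ``alpha``
    are reported as ``uncertain``.  Columns: ``component`` (argmax),
    ``signal_prob``, ``designation``, and one posterior column per
    component (``post_0``..).
    """
    if rule not in ("max_prob", "threshold"):
        raise ValueError(f"unknown classification rule {rule!r}")
    post = posterior_probs(model, abs_diffs)
    argmax = np.argmax(post, axis=1)
    sig_idx = sorted(signal_components)
    signal_prob = post[:, sig_idx].sum(axis=1) if sig_idx else np.zeros(len(post))
    in_signal = np.isin(argmax, sig_idx)
    if rule == "max_prob":
        is_aei = in_signal
    else:
        is_aei = signal_prob >= threshold
    designation = np.where(
        is_aei, "AEI", np.where(signal_prob > alpha, "uncertain", "no_AEI")
    )
    out = pd.DataFrame(
        {
            "component": argmax,
            "signal_prob": signal_prob,
            "designation": designation,
        }
    )
    for k in range(model.K):
        out[f"post_{k}"] = post[:, k]
    return out
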