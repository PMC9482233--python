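"""Partial credit model: probabilities, CML item estimation, person locations.

The partial credit model (PCM) places persons (theta) and item category
thresholds (delta) on one logit scale:

    P(X_i = x | theta) = exp(x*theta - beta_ix) / sum_j exp(j*theta - beta_ij)

with cumulative thresholds beta_ix = delta_i1 + ... + delta_ix and
beta_i0 = 0. Item parameters are estimated by conditional maximum
likelihood (CML): conditioning on each person's raw total score removes the
person parameters entirely, so the estimates do not depend on the person
distribution — the invariance property that motivates Rasch modelling.
The conditional likelihood is evaluated through elementary symmetric
functions computed by a log-domain item-by-item convolution.

Identifiability: the conditional likelihood is invariant to adding one
constant to every threshold; the gauge is fixed by centring so the mean
item location (mean of each item's thresholds, averaged over items) is 0.
Standard errors come from the pseudo-inverse of the observed conditional
information, which resolves the same flat direction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data_model import ResponseMatrix

__all__ = [
    "ItemParameters",
    "PersonEstimates",
    "category_probabilities",
    "expected_score_and_variance",
    "elementary_symmetric_functions",
    "estimate_item_parameters",
    "estimate_person_locations",
]

_EXTREME_ADJUST = 0.3  # raw-score adjustment toward the interior for 0/max scores


class ConvergenceError(RuntimeError):
    pass


class NullCategoryError(ValueError):
    pass


@dataclasses.dataclass
class ItemParameters:
    """Per-item threshold estimates (logits) with standard errors.

    ``thresholds[item]`` is the vector (delta_1 .. delta_m); the item
    location is its mean. The centring constraint makes the mean item
    location 0 over all items.
    """

    items: tuple[str, ...]
    thresholds: dict[str, np.ndarray]
    se: dict[str, np.ndarray]
    centering: str = "mean item location = 0"

    def item_location(self, item: str) -> float:
        return float(np.mean(self.thresholds[item]))

    def max_score(self, item: str) -> int:
        return len(self.thresholds[item])

    def total_max(self) -> int:
        return int(sum(len(self.thresholds[i]) for i in self.items))

    def all_thresholds(self) -> np.ndarray:
        return np.concatenate([self.thresholds[i] for i in self.items])


@dataclasses.dataclass
class PersonEstimates:
    """Per-person latent locations (logits) from maximum likelihood.

    Raw total score is sufficient for theta under the PCM, so persons with
    equal raw scores get identical estimates. Extreme raw scores (0 or the
    maximum) have no finite ML estimate; they are score-adjusted toward the
    interior and flagged.
    """

    person_ids: np.ndarray
    raw_scores: np.ndarray
    theta: np.ndarray
    se: np.ndarray
    extreme: np.ndarray  # bool


def _betas(thresholds: np.ndarray) -> np.ndarray:
    """Cumulative thresholds beta_0..beta_m (beta_0 = 0)."""
    return np.concatenate([[0.0], np.cumsum(thresholds)])


def category_probabilities(theta: float | np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """PCM category probabilities at theta for one item.

    Returns shape (m+1,) for scalar theta, else (len(theta), m+1).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    beta = _betas(thresholds)
    x = np.arange(len(beta))
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    logits = np.outer(t, x) - beta  # (n, m+1)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if np.isscalar(theta) or np.ndim(theta) == 0 else p


def expected_score_and_variance(
    theta: float | np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model-expected item score E[X] and variance V[X] at theta."""
    p = category_probabilities(theta, thresholds)
    x = np.arange(p.shape[-1])
    e = p @ x
    v = p @ (x ** 2) - e ** 2
    return e, v


def _log_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Log-domain polynomial convolution: log of conv(exp(a), exp(b))."""
    out = np.full(len(a) + len(b) - 1, -np.inf)
    for x in range(len(b)):
        np.logaddexp(out[x:x + len(a)], a + b[x], out=out[x:x + len(a)])
    return out


def _log_weights(thresholds_list: list[np.ndarray]) -> list[np.ndarray]:
    """Per-item log ESF weights: index x holds -beta_ix."""
    return [-_betas(t) for t in thresholds_list]


def _log_esf(log_w: list[np.ndarray]) -> np.ndarray:
    g = np.zeros(1)
    for lw in log_w:
        g = _log_conv(g, lw)
    return g


def elementary_symmetric_functions(thresholds_list: list[np.ndarray]) -> np.ndarray:
    """Elementary symmetric functions gamma_r of a PCM item set.

    gamma_r sums exp(-sum_i beta_i,x_i) over all response patterns with
    total score r; gamma_0 = 1. Computed by recursive item-by-item
    convolution in the log domain to avoid overflow.
    """
    return np.exp(_log_esf(_log_weights([np.asarray(t, float) for t in thresholds_list])))


def _prefix_suffix(log_w: list[np.ndarray]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    k = len(log_w)
    prefix = [np.zeros(1)]
    for i in range(k):
        prefix.append(_log_conv(prefix[-1], log_w[i]))
    suffix = [np.zeros(1)]
    for i in range(k - 1, -1, -1):
        suffix.append(_log_conv(suffix[-1], log_w[i]))
    suffix.reverse()  # suffix[i] = conv of items i..k-1; suffix[k] = unit
    return prefix, suffix


def _score_table(rm: ResponseMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-extreme score counts n_r and observed category counts O[i, x]."""
    totals = rm.total_scores()
    max_total = int(rm.max_scores().sum())
    interior = (totals > 0) & (totals < max_total)
    n_r = np.bincount(totals[interior], minlength=max_total + 1).astype(float)
    counts = np.zeros((rm.n_items, int(rm.max_scores().max()) + 1))
    resp = rm.responses[interior]
    for j in range(rm.n_items):
        counts[j] = np.bincount(resp[:, j], minlength=counts.shape[1])
    return n_r, counts, totals


def _neg_cll_and_grad(
    delta_flat: np.ndarray,
    m_list: list[int],
    n_r: np.ndarray,
    obs_counts: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative conditional log-likelihood and gradient in delta-space."""
    # unpack
    thresholds, pos = [], 0
    for m in m_list:
        thresholds.append(delta_flat[pos:pos + m])
        pos += m
    log_w = _log_weights(thresholds)
    prefix, suffix = _prefix_suffix(log_w)
    log_gamma = prefix[-1]
    scores = np.flatnonzero(n_r > 0)
    # log-likelihood: - sum_i sum_x O[i,x] * beta_ix - sum_r n_r log gamma_r
    ll = -np.dot(n_r[scores], log_gamma[scores])
    grad_beta = []  # d(-ll)/d(beta_ix), x = 1..m_i
    for i, m in enumerate(m_list):
        beta = _betas(thresholds[i])
        ll -= np.dot(obs_counts[i, 1:m + 1], beta[1:])
        lg_minus = _log_conv(prefix[i], suffix[i + 1])  # ESF without item i
        # expected category counts: sum_r n_r * pi_{i,x}(r)
        exp_counts = np.zeros(m + 1)
        for x in range(m + 1):
            r = scores
            valid = (r - x >= 0) & (r - x < len(lg_minus))
            rv = r[valid]
            lp = -beta[x] + lg_minus[rv - x] - log_gamma[rv]
            exp_counts[x] = np.dot(n_r[rv], np.exp(lp))
        # d ll / d beta_ix = -O[i,x] + E[i,x]  (for the minimized -ll: O - E ... )
        grad_beta.append(obs_counts[i, 1:m + 1] - exp_counts[1:])
    # chain to delta: d/d delta_ik = sum_{x>=k} d/d beta_ix
    grad = np.concatenate([np.cumsum(g[::-1])[::-1] for g in grad_beta])
    return -ll, grad


def _center(delta_flat: np.ndarray, m_list: list[int]) -> np.ndarray:
    """Shift all thresholds so the mean item location is 0 (the gauge)."""
    locs, pos = [], 0
    for m in m_list:
        locs.append(delta_flat[pos:pos + m].mean())
        pos += m
    return delta_flat - np.mean(locs)


def estimate_item_parameters(
    rm: ResponseMatrix,
    gtol: float = 1e-8,
    max_newton: int = 200,
    compute_se: bool = True,
) -> ItemParameters:
    """CML estimation of PCM thresholds from complete-case data.

    Persons with extreme total scores carry no conditional information and
    are ignored. Every category of every item must be observed at least
    once; otherwise a ``NullCategoryError`` names the item and category
    (collapse categories or resample). Optimization: L-BFGS warm start on
    the concave conditional log-likelihood, then Newton polish to gradient
    norm ``gtol``; standard errors from the pseudo-inverse of the observed
    conditional information (sum-zero gauge).
    """
    if rm.is_missing().any():
        raise ValueError("item estimation requires complete-case data")
    m_list = [rm.spec.max_internal(i) for i in rm.spec.items]
    n_r, obs_counts, _ = _score_table(rm)
    for i, item in enumerate(rm.spec.items):
        for x in range(m_list[i] + 1):
            if obs_counts[i, x] == 0:
                raise NullCategoryError(
                    f"category {x} of item {item!r} is never observed "
                    "(among non-extreme persons); collapse categories or "
                    "use a larger sample"
                )
    p = sum(m_list)
    x0 = np.zeros(p)
    res = minimize(
        _neg_cll_and_grad, x0, args=(m_list, n_r, obs_counts),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    delta = res.x
    # Newton polish (guards the L-BFGS tolerance; conditional LL is concave)
    trace = []
    for it in range(max_newton):
        f, g = _neg_cll_and_grad(delta, m_list, n_r, obs_counts)
        gnorm = np.linalg.norm(g)
        trace.append(gnorm)
        if gnorm <= gtol * max(1.0, np.sum(n_r)):
            break
        H = _num_hessian(delta, m_list, n_r, obs_counts)
        u = np.ones(p) / np.sqrt(p)  # flat gauge direction
        kappa = np.trace(H) / p
        step = np.linalg.solve(H + kappa * np.outer(u, u), g)
        delta = delta - step
    else:
        raise ConvergenceError(f"Newton did not converge; |grad| trace: {trace[-5:]}")
    delta = _center(delta, m_list)
    se_flat = np.full(p, np.nan)
    if compute_se:
        H = _num_hessian(delta, m_list, n_r, obs_counts)
        # deflate the flat gauge direction exactly, then project it back out
        u = np.ones(p) / np.sqrt(p)
        kappa = np.trace(H) / p
        cov = np.linalg.inv(H + kappa * np.outer(u, u))
        proj = np.eye(p) - np.outer(u, u)
        cov = proj @ cov @ proj
        se_flat = np.sqrt(np.clip(np.diag(cov), 0, None))
    thresholds, se, pos = {}, {}, 0
    for item, m in zip(rm.spec.items, m_list):
        thresholds[item] = delta[pos:pos + m].copy()
        se[item] = se_flat[pos:pos + m].copy()
        pos += m
    return ItemParameters(tuple(rm.spec.items), thresholds, se)


def _num_hessian(delta, m_list, n_r, obs_counts, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the negative conditional LL from its gradient."""
    p = len(delta)
    H = np.empty((p, p))
    for j in range(p):
        dp = delta.copy(); dp[j] += h
        dm = delta.copy(); dm[j] -= h
        _, gp = _neg_cll_and_grad(dp, m_list, n_r, obs_counts)
        _, gm = _neg_cll_and_grad(dm, m_list, n_r, obs_counts)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _theta_for_score(r_adj: float, thresholds_list: list[np.ndarray]) -> tuple[float, float]:
    """Solve E[total | theta] = r_adj by safeguarded Newton; return (theta, se)."""
    theta, lo, hi = 0.0, -50.0, 50.0
    for _ in range(200):
        e = v = 0.0
        for t in thresholds_list:
            ei, vi = expected_score_and_variance(theta, t)
            e += float(ei); v += float(vi)
        diff = e - r_adj
        if abs(diff) < 1e-10:
            break
        if diff > 0:
            hi = min(hi, theta)
        else:
            lo = max(lo, theta)
        step = diff / max(v, 1e-12)
        theta_new = theta - step
        if not lo < theta_new < hi:
            theta_new = (lo + hi) / 2
        theta = theta_new
    v = sum(float(expected_score_and_variance(theta, t)[1]) for t in thresholds_list)
    return theta, 1.0 / np.sqrt(max(v, 1e-12))


def estimate_person_locations(rm: ResponseMatrix, ip: ItemParameters) -> PersonEstimates:
    """ML person locations given fixed item parameters.

    theta-hat solves E[total score | theta] = observed raw score; the SE is
    the inverse square root of the test information at theta-hat. Extreme
    raw scores are adjusted by 0.3 score units toward the interior and
    flagged (no finite ML estimate exists for them).
    """
    thresholds_list = [ip.thresholds[i] for i in rm.spec.items]
    totals = rm.total_scores()
    max_total = ip.total_max()
    extreme = (totals == 0) | (totals == max_total)
    theta = np.empty(rm.n_persons)
    se = np.empty(rm.n_persons)
    cache: dict[float, tuple[float, float]] = {}
    for n in range(rm.n_persons):
        r = float(totals[n])
        if totals[n] == 0:
            r = _EXTREME_ADJUST
        elif totals[n] == max_total:
            r = max_total - _EXTREME_ADJUST
        if r not in cache:
            cache[r] = _theta_for_score(r, thresholds_list)
        theta[n], se[n] = cache[r]
    return PersonEstimates(rm.person_ids.copy(), totals, theta, se, extreme)
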