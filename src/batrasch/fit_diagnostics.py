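"""Residual-based fit diagnostics for the partial credit model.

Standardized residuals z_ni = (x_ni - E[x_ni]) / sqrt(V[x_ni]) are computed
at the ML person estimate theta-hat. Item and person fit residuals
standardize the sum of squared residuals by its model-implied mean and
variance and map it to an approximately unit-normal scale with a
Wilson-Hilferty cube-root transform, so under the model the collection of
fit residuals has mean near 0 and SD near 1; strongly negative values mean
over-discrimination (too Guttman-like), positive values noise/
under-discrimination.

One subtlety matters for calibration: because theta-hat is a deterministic
function of the raw total score (which is sufficient under the PCM), the
naive moments E[z^2] = 1, Var(z^2) = kurtosis - 1 are wrong once the model
is fitted — the raw residuals of a person sum to zero across items and the
conditional response distribution given the total differs from the
unconditional one. For item fit the moments of z^2 are therefore computed
EXACTLY under the conditional distribution of each response given the
person's total score (via the elementary-symmetric-function recursions),
which is also the distribution the CML estimates target. For person fit
(a sum across items within one person, where conditional cross-item
covariances would be required) a first-order linearization of the
estimation shrinkage, E[z^2] ~= 1 - V_i/sum_j V_j, is used instead.

Item chi-square tests compare residual sums across class intervals of the
latent trait (persons grouped by theta-hat), with g-1 degrees of freedom
per item and Bonferroni adjustment across items at base alpha 0.01.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ResponseMatrix
from .pcm_core import (
    ItemParameters,
    PersonEstimates,
    _betas,
    _log_conv,
    _log_weights,
    _prefix_suffix,
    category_probabilities,
)

__all__ = [
    "ResidualMatrix",
    "FitReport",
    "standardized_residuals",
    "fit_residuals",
    "assign_class_intervals",
    "item_chi_square",
    "threshold_order_check",
    "salzberger_threshold_test",
    "default_n_intervals",
    "fit_report",
]


@dataclasses.dataclass
class ResidualMatrix:
    """Standardized residuals for non-extreme persons, plus the moment
    tables needed to calibrate fit statistics."""

    items: tuple[str, ...]
    z: np.ndarray                 # (n_nonextreme, k)
    person_rows: np.ndarray       # row indices into the original matrix
    theta: np.ndarray             # theta-hat of the retained persons
    ez2: np.ndarray               # (n, k) E[z^2 | total score], exact (item fit)
    vz2: np.ndarray               # (n, k) Var(z^2 | total score), exact (item fit)
    ez2_lin: np.ndarray           # (n, k) linearized E[z^2] (person fit)
    vz2_lin: np.ndarray           # (n, k) linearized Var(z^2) (person fit)
    var_correction: np.ndarray    # (k,) variance absorbed by the item's own
                                  # estimated parameters (c' I^-1 c)


def standardized_residuals(
    rm: ResponseMatrix, ip: ItemParameters, pe: PersonEstimates
) -> ResidualMatrix:
    """Standardized response residuals at theta-hat (non-extreme persons)."""
    keep = np.flatnonzero(~pe.extreme)
    theta = pe.theta[keep]
    raw = pe.raw_scores[keep]
    n, k = len(keep), rm.n_items
    z = np.empty((n, k))
    var = np.empty((n, k))
    kurt_num = np.empty((n, k))  # E[(x - E)^4] at theta-hat
    e_all = np.empty((n, k))
    for j, item in enumerate(rm.spec.items):
        th = ip.thresholds[item]
        p = category_probabilities(theta, th)  # (n, m+1)
        xcat = np.arange(p.shape[1])
        e = p @ xcat
        v = p @ xcat ** 2 - e ** 2
        m4 = np.einsum("nc,nc->n", p, (xcat[None, :] - e[:, None]) ** 4)
        x = rm.responses[keep, j]
        z[:, j] = (x - e) / np.sqrt(v)
        var[:, j] = v
        kurt_num[:, j] = m4
        e_all[:, j] = e
    # linearized moments (person fit): ML theta zeroes the summed raw residual
    vsum = var.sum(axis=1, keepdims=True)
    shrink = 1.0 - var / vsum
    kurt = kurt_num / var ** 2
    vz2_lin = np.clip(kurt - 1.0, 1e-12, None) * shrink ** 2
    # exact conditional moments of z^2 given the raw total score (item fit)
    ez2, vz2, var_corr = _conditional_z2_moments(rm, ip, raw, theta, e_all, var)
    return ResidualMatrix(tuple(rm.spec.items), z, keep, theta,
                          ez2, vz2, shrink, vz2_lin, var_corr)


def _conditional_z2_moments(
    rm: ResponseMatrix,
    ip: ItemParameters,
    raw: np.ndarray,
    theta: np.ndarray,
    e_all: np.ndarray,
    var: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """E[z^2 | r], Var(z^2 | r) per person-item, and the per-item variance
    absorbed by estimating the item's own thresholds.

    The conditional category distribution P(X_i = x | total = r) is exact
    under CML (computed via ESF recursions), and z is a deterministic
    function of (x, r), so the moments are exact. Because the CML score
    equations force observed category counts to equal their conditional
    expectations, the fitted item's sum of z^2 loses the variance of its
    projection onto the item's own sufficient statistics: c' I^-1 c with
    c = sum_n Cov(z^2, category indicators | r_n) and I the item's own
    information block (cross-item information coupling neglected).
    """
    thresholds = [ip.thresholds[i] for i in rm.spec.items]
    log_w = _log_weights(thresholds)
    prefix, suffix = _prefix_suffix(log_w)
    log_gamma = prefix[-1]
    scores, inv = np.unique(raw, return_inverse=True)
    n_score = np.bincount(inv)
    n, k = e_all.shape
    m1 = np.empty((len(scores), k))
    m2 = np.empty((len(scores), k))
    var_corr = np.zeros(k)
    # representative person per score (theta, e, v identical within a score)
    rep = np.zeros(len(scores), dtype=int)
    rep[inv] = np.arange(n)
    for j in range(k):
        beta = _betas(thresholds[j])
        lg_minus = _log_conv(prefix[j], suffix[j + 1])
        mcat = len(beta) - 1
        cvec = np.zeros(mcat)          # sum_n Cov(z^2, 1{x=c} | r_n), c=1..m
        info = np.zeros((mcat, mcat))  # sum_n Var(category indicators | r_n)
        for si, r in enumerate(scores):
            xs = np.arange(max(0, r - (len(lg_minus) - 1)), min(mcat, r) + 1)
            lp = -beta[xs] + lg_minus[r - xs] - log_gamma[r]
            p = np.exp(lp)
            p /= p.sum()
            i0 = rep[si]
            zv = (xs - e_all[i0, j]) / np.sqrt(var[i0, j])
            z2 = zv ** 2
            m1[si, j] = p @ z2
            m2[si, j] = p @ z2 ** 2
            w = n_score[si]
            pfull = np.zeros(mcat + 1)
            pfull[xs] = p
            z2full = np.zeros(mcat + 1)
            z2full[xs] = z2
            cvec += w * (pfull[1:] * (z2full[1:] - m1[si, j]))
            info += w * (np.diag(pfull[1:]) - np.outer(pfull[1:], pfull[1:]))
        try:
            var_corr[j] = float(cvec @ np.linalg.solve(info, cvec))
        except np.linalg.LinAlgError:
            var_corr[j] = 0.0
    ez2 = m1[inv]
    vz2 = np.clip(m2[inv] - m1[inv] ** 2, 1e-12, None)
    return ez2, vz2, var_corr


def _wilson_hilferty(y: float, mu: float, var: float) -> float:
    """Map a sum of squares with model mean/variance to a unit-normal scale."""
    nu = 2.0 * mu ** 2 / var  # effective chi-square df matching mean/variance
    c = 2.0 / (9.0 * nu)
    return (np.cbrt(max(y, 0.0) / mu) - (1.0 - c)) / np.sqrt(c)


def fit_residuals(res: ResidualMatrix) -> tuple[pd.Series, np.ndarray]:
    """Item and person fit residuals (approximately N(0,1) under the model)."""
    z2 = res.z ** 2
    item_fr = pd.Series(
        [_wilson_hilferty(
            z2[:, j].sum(), res.ez2[:, j].sum(),
            max(res.vz2[:, j].sum() - res.var_correction[j],
                0.1 * res.vz2[:, j].sum()))
         for j in range(z2.shape[1])],
        index=list(res.items), name="fit_residual",
    )
    person_fr = np.array(
        [_wilson_hilferty(z2[i].sum(), res.ez2_lin[i].sum(), res.vz2_lin[i].sum())
         for i in range(z2.shape[0])]
    )
    return item_fr, person_fr


def default_n_intervals(n_non_extreme: int) -> int:
    """Common heuristic: at most 10 intervals, at least 50 persons each."""
    return max(2, min(10, n_non_extreme // 50))


def assign_class_intervals(pe: PersonEstimates, g: int) -> np.ndarray:
    """Cut non-extreme persons into g contiguous near-equal intervals by
    theta-hat; tied theta values stay in one interval. Returns labels
    0..g-1 aligned with the non-extreme persons (order of pe)."""
    theta = pe.theta[~pe.extreme]
    return _intervals_of(theta, g)


def _intervals_of(theta: np.ndarray, g: int) -> np.ndarray:
    if g < 2:
        raise ValueError("need at least 2 class intervals")
    uniq = np.unique(theta)
    if len(uniq) < g:
        raise ValueError(
            f"only {len(uniq)} distinct person locations; cannot form {g} intervals"
        )
    order = np.argsort(theta, kind="stable")
    n = len(theta)
    labels = np.empty(n, dtype=int)
    # target cut points at equal counts, then push ties into one interval
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    raw = (ranks * g) // n
    # persons sharing a theta get the modal (lowest) raw label among them
    labels = raw.copy()
    for v in uniq:
        mask = theta == v
        labels[mask] = labels[mask].min()
    # re-densify labels to 0..g'-1 (tie-merging may empty an interval)
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def item_chi_square(res: ResidualMatrix, intervals: np.ndarray) -> pd.DataFrame:
    """Per-item class-interval chi-square: sum over intervals of
    (sum of z in interval)^2 / interval size, df = g - 1."""
    g = intervals.max() + 1
    counts = np.bincount(intervals, minlength=g)
    if (counts == 0).any():
        raise ValueError("empty class interval")
    rows = []
    for j, item in enumerate(res.items):
        chi2 = 0.0
        for c in range(g):
            m = intervals == c
            chi2 += res.z[m, j].sum() ** 2 / counts[c]
        df = g - 1
        rows.append((item, chi2, df, stats.chi2.sf(chi2, df)))
    return pd.DataFrame(rows, columns=["item", "chi2", "df", "p"]).set_index("item")


def threshold_order_check(ip: ItemParameters) -> pd.DataFrame:
    """Flag items whose estimated thresholds are not non-decreasing."""
    rows = []
    for item in ip.items:
        th = ip.thresholds[item]
        bad = np.flatnonzero(np.diff(th) < 0)
        rows.append((item, len(bad) == 0,
                     None if len(bad) == 0 else (int(bad[0]) + 1, int(bad[0]) + 2)))
    return pd.DataFrame(rows, columns=["item", "ordered", "disordered_pair"]).set_index("item")


def salzberger_threshold_test(
    delta_k: float, se_k: float, delta_k1: float, se_k1: float, alpha: float = 0.01
) -> dict:
    """Hybrid hypothesis test of true threshold ordering for an adjacent pair.

    z = (delta_{k+1} - delta_k) / sqrt(se_k^2 + se_{k+1}^2). "ordered" if z
    is significantly positive, "disordered" if significantly negative, else
    "undecided" (the observed reversal may be sampling noise).
    """
    if se_k <= 0 or se_k1 <= 0:
        raise ValueError("standard errors must be positive")
    z = (delta_k1 - delta_k) / np.hypot(se_k, se_k1)
    crit = stats.norm.ppf(1 - alpha)
    if z > crit:
        verdict = "ordered"
    elif z < -crit:
        verdict = "disordered"
    else:
        verdict = "undecided"
    return {"z": float(z), "verdict": verdict, "alpha": alpha}


@dataclasses.dataclass
class FitReport:
    """Aggregate item/person fit: per-item table, per-person fit residuals,
    and overall summary in the style of a Rasch analysis report."""

    item_table: pd.DataFrame      # fit residual, chi2, df, p, bonferroni flag, ordered
    person_fit_residuals: np.ndarray
    summary: dict                 # means/SDs, total chi2/df/p, alpha used


def fit_report(
    rm: ResponseMatrix,
    ip: ItemParameters,
    pe: PersonEstimates,
    n_intervals: int | None = None,
    alpha: float = 0.01,
) -> FitReport:
    """Full fit diagnostics: residuals, fit residuals, chi-squares, ordering."""
    res = standardized_residuals(rm, ip, pe)
    item_fr, person_fr = fit_residuals(res)
    g = n_intervals or default_n_intervals(len(res.person_rows))
    intervals = _intervals_of(res.theta, g)
    chi = item_chi_square(res, intervals)
    order = threshold_order_check(ip)
    k = len(ip.items)
    bonf = alpha / k
    table = pd.concat([item_fr, chi, order[["ordered"]]], axis=1)
    table["significant"] = table["p"] < bonf
    total_chi2 = float(chi["chi2"].sum())
    total_df = int(chi["df"].sum())
    summary = {
        "item_fit_mean": float(item_fr.mean()),
        "item_fit_sd": float(item_fr.std(ddof=1)),
        "person_fit_mean": float(person_fr.mean()),
        "person_fit_sd": float(person_fr.std(ddof=1)),
        "total_chi2": total_chi2,
        "total_df": total_df,
        "total_p": float(stats.chi2.sf(total_chi2, total_df)),
        "alpha": alpha,
        "bonferroni_alpha": bonf,
        "n_intervals": int(intervals.max() + 1),
    }
    return FitReport(table, person_fr, summary)
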