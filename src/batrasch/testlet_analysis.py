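"""Testlet (super-item) analysis: variance decomposition and reliability.

Summing the items of each subscale into one polytomous super-item absorbs
the local dependency among them; re-fitting the Rasch model on the four
testlets then isolates the common (general-factor) variance. Coefficient
alpha on the 23 item columns bounds the non-error variance; alpha on the 4
testlet columns isolates the common true-score variance, so

    nonerror = alpha_items,  common = alpha_testlets,
    unique   = alpha_items - alpha_testlets,  error = 1 - alpha_items,

and the ratio common/nonerror says how much of the systematic variance a
single total score captures. Subscale latent correlations are estimated by
fitting each subscale separately and disattenuating the person-estimate
correlations by the subscale PSI values.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd

from .data_model import ResponseMatrix, ScaleSpec
from .pcm_core import PersonEstimates, estimate_item_parameters, estimate_person_locations

__all__ = [
    "build_testlets",
    "collapse_unobserved_categories",
    "person_separation_index",
    "coefficient_alpha",
    "variance_decomposition",
    "latent_correlations",
]


def build_testlets(rm: ResponseMatrix, spec: ScaleSpec | None = None) -> ResponseMatrix:
    """Sum each subscale's items into one polytomous super-item.

    The testlet's internal score range is 0..sum of the member items' m_i
    (0..32 for an 8-item, 5-category subscale); the testlet total equals
    the item-level total for every person.
    """
    spec = spec or rm.spec
    if rm.is_missing().any():
        raise ValueError("testlets require complete cases")
    cols, n_cat, sub_of = [], {}, {}
    for s in spec.subscales:
        idx = [spec.items.index(i) for i in spec.items_of(s)]
        cols.append(rm.responses[:, idx].sum(axis=1))
        n_cat[s] = int(sum(spec.max_internal(i) for i in spec.items_of(s))) + 1
        sub_of[s] = s
    tspec = ScaleSpec(
        items=tuple(spec.subscales), subscale_of=sub_of, n_categories=n_cat,
        min_code=0, max_code=max(n_cat.values()) - 1,
    )
    return ResponseMatrix(
        tspec, np.column_stack(cols), rm.person_ids.copy(),
        None if rm.covariates is None else rm.covariates.copy(),
    )


def collapse_unobserved_categories(
    rm: ResponseMatrix,
) -> tuple[ResponseMatrix, dict[str, np.ndarray]]:
    """Collapse categories never observed among non-extreme persons.

    CML needs every category observed; long testlet score ranges are
    sparse at moderate n. Each unobserved category merges into the next
    lower observed one. Returns the recoded matrix and, per item, the map
    from old to new internal codes.
    """
    totals = rm.total_scores()
    interior = (totals > 0) & (totals < rm.max_scores().sum())
    resp = rm.responses.copy()
    mapping: dict[str, np.ndarray] = {}
    n_cat = {}
    for j, item in enumerate(rm.spec.items):
        m = rm.spec.max_internal(item)
        seen = np.bincount(resp[interior, j], minlength=m + 1) > 0
        new_code = np.cumsum(seen) - 1
        new_code = np.clip(new_code, 0, None)  # leading unobserved -> 0
        mapping[item] = new_code
        resp[:, j] = new_code[resp[:, j]]
        n_cat[item] = int(new_code.max()) + 1
    spec2 = ScaleSpec(
        items=rm.spec.items, subscale_of=dict(rm.spec.subscale_of),
        n_categories=n_cat, min_code=rm.spec.min_code, max_code=rm.spec.max_code,
    )
    return ResponseMatrix(spec2, resp, rm.person_ids.copy(),
                          None if rm.covariates is None else rm.covariates.copy()), mapping


def person_separation_index(pe: PersonEstimates) -> float:
    """PSI = (var(theta-hat) - mean(SE^2)) / var(theta-hat), floored at 0.

    The Rasch analogue of reliability: the share of observed person-
    estimate variance not attributable to estimation error. Non-extreme
    persons only.
    """
    ok = ~pe.extreme
    if ok.sum() < 2:
        raise ValueError("need at least two non-extreme persons")
    v = float(np.var(pe.theta[ok], ddof=1))
    if v <= 0:
        warnings.warn("zero person variance; PSI reported as 0")
        return 0.0
    return max(0.0, (v - float(np.mean(pe.se[ok] ** 2))) / v)


def coefficient_alpha(columns: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha over score columns (items or testlets)."""
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 columns and >= 2 persons")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1 - np.var(x, axis=0, ddof=1).sum() / total_var))


def variance_decomposition(alpha_items: float, alpha_testlets: float) -> dict[str, float]:
    """Split total variance using the two alphas (items vs testlets)."""
    if not (np.isfinite(alpha_items) and np.isfinite(alpha_testlets)):
        raise ValueError("alphas must be finite")
    if alpha_items <= 0:
        raise ValueError("alpha_items <= 0; common/non-error ratio undefined")
    return {
        "nonerror_prop": alpha_items,
        "common_prop": alpha_testlets,
        "unique_prop": alpha_items - alpha_testlets,
        "error_prop": 1.0 - alpha_items,
        "common_over_nonerror": alpha_testlets / alpha_items,
    }


def latent_correlations(rm: ResponseMatrix, spec: ScaleSpec | None = None) -> dict:
    """Observed and disattenuated correlations between subscale locations.

    Each subscale is fitted as its own PCM; persons are located per
    subscale; pairwise Pearson correlations of the estimates are corrected
    for attenuation with the subscale PSIs, r* = r / sqrt(PSI_a PSI_b),
    capped at 1. Persons extreme on a subscale are dropped pairwise.
    """
    spec = spec or rm.spec
    theta, extreme, psi = {}, {}, {}
    for s in spec.subscales:
        sub, _ = collapse_unobserved_categories(rm.subset_items(list(spec.items_of(s))))
        ip = estimate_item_parameters(sub, compute_se=False)
        pe = estimate_person_locations(sub, ip)
        theta[s] = pe.theta
        extreme[s] = pe.extreme
        psi[s] = person_separation_index(pe)
    subs = list(spec.subscales)
    observed = pd.DataFrame(np.eye(len(subs)), index=subs, columns=subs)
    disattenuated = observed.copy()
    vals = []
    for a, b in itertools.combinations(subs, 2):
        ok = ~(extreme[a] | extreme[b])
        r = float(np.corrcoef(theta[a][ok], theta[b][ok])[0, 1])
        observed.loc[a, b] = observed.loc[b, a] = r
        if psi[a] <= 0 or psi[b] <= 0:
            warnings.warn(f"subscale PSI <= 0; pair {a}-{b} excluded")
            disattenuated.loc[a, b] = disattenuated.loc[b, a] = np.nan
            continue
        rstar = min(1.0, r / np.sqrt(psi[a] * psi[b]))
        disattenuated.loc[a, b] = disattenuated.loc[b, a] = rstar
        vals.append(rstar)
    return {
        "observed": observed,
        "disattenuated": disattenuated,
        "average_disattenuated": float(np.mean(vals)) if vals else np.nan,
        "psi": psi,
    }
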