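"""PCM response simulation with subscale structure, dependency and DIF.

The generator is the data-generating counterpart of the estimation code:
persons receive subscale-specific latent locations drawn from a
multivariate normal (perfectly correlated by default, which collapses to
the strictly unidimensional PCM), and every item is answered by sampling from
its PCM category distribution at the person's location for that item's
subscale. Local dependency beyond the shared latent structure can be
injected pairwise (item j copies item i's category with some probability),
and differential item functioning can be injected as a uniform threshold
shift or a non-uniform slope multiplier for a focal group.

Defaults emulate a large occupational cohort with fairly low burnout:
23 BAT items with the bundled published thresholds, person locations
Normal(-0.95, 0.63) on the logit scale, n = 800 per sample. The floor
effects seen in such cohorts (top categories rarely used) emerge from the
thresholds and the low person mean; no extra censoring is applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import bat
from .data_model import ResponseMatrix, ScaleSpec, bat_spec
from .pcm_core import category_probabilities

__all__ = ["DIFSpec", "DependencySpec", "GeneratorConfig", "default_bat_config", "generate"]


@dataclasses.dataclass
class DIFSpec:
    """Differential item functioning to inject for a focal group.

    ``uniform`` DIF shifts the item's thresholds by ``location_shift``
    logits for the focal group; ``non-uniform`` DIF multiplies the focal
    group's theta by ``slope_factor`` for that item only.
    """

    item: str
    group_variable: str = "group"
    focal_level: str = "B"
    kind: str = "uniform"  # "uniform" | "non-uniform"
    location_shift: float = 0.0
    slope_factor: float = 1.5


@dataclasses.dataclass
class DependencySpec:
    """Response dependency: item ``target`` copies ``source`` with prob rho."""

    source: str
    target: str
    rho: float


@dataclasses.dataclass
class GeneratorConfig:
    spec: ScaleSpec
    item_thresholds: dict[str, np.ndarray]
    person_mean: float = bat.BAT_PERSON_MEAN
    person_sd: float = bat.BAT_PERSON_SD
    n_persons: int = 800
    latent_corr: np.ndarray | None = None  # subscales x subscales; None = all-ones
    # (a single shared theta, i.e. the strictly unidimensional PCM)
    dif: DIFSpec | None = None
    dependency: DependencySpec | None = None
    age_range: tuple[int, int] = (25, 70)
    seed: int = 0

    def corr_matrix(self) -> np.ndarray:
        s = len(self.spec.subscales)
        if self.latent_corr is None:
            return np.ones((s, s))  # one shared theta: unidimensional
        c = np.asarray(self.latent_corr, dtype=float)
        if c.shape != (s, s) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
            raise ValueError("latent_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("latent_corr is not positive semi-definite")
        return c


def default_bat_config(**overrides) -> GeneratorConfig:
    """The bundled BAT generator: published thresholds, theta ~ N(-0.95, 0.63),
    a single shared latent dimension, n = 800."""
    cfg = GeneratorConfig(
        spec=bat_spec(),
        item_thresholds={k: np.array(v) for k, v in bat.BAT_THRESHOLDS.items()},
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def uniform_offdiag_corr(spec: ScaleSpec, rho: float) -> np.ndarray:
    """Equicorrelation matrix for the subscale latent locations."""
    s = len(spec.subscales)
    return np.full((s, s), rho) + (1 - rho) * np.eye(s)


def generate(config: GeneratorConfig) -> ResponseMatrix:
    """Draw a ResponseMatrix from the configured multi-subscale PCM."""
    spec = config.spec
    corr = config.corr_matrix()  # validates before any sampling
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    s = len(spec.subscales)
    # subscale-specific person locations
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(s))
    z = rng.standard_normal((n, s)) @ chol.T
    theta = config.person_mean + config.person_sd * z  # (n, s)
    sub_index = {sub: k for k, sub in enumerate(spec.subscales)}

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    groups = np.where(ages <= np.median(ages), "A", "B")

    dif = config.dif
    resp = np.empty((n, len(spec.items)), dtype=int)
    for j, item in enumerate(spec.items):
        th = np.asarray(config.item_thresholds[item], dtype=float)
        t = theta[:, sub_index[spec.subscale_of[item]]].copy()
        th_matrix = None
        if dif is not None and dif.item == item:
            focal = _focal_mask(dif, groups, ages)
            if dif.kind == "uniform":
                if dif.location_shift != 0.0:
                    th_matrix = np.tile(th, (n, 1))
                    th_matrix[focal] += dif.location_shift
            else:
                if dif.slope_factor != 1.0:
                    t[focal] = (config.person_mean
                                + dif.slope_factor * (t[focal] - config.person_mean))
        if th_matrix is None:
            p = category_probabilities(t, th)
        else:
            p = np.vstack([category_probabilities(t[i], th_matrix[i]) for i in range(n)])
        u = rng.random(n)
        resp[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)

    if config.dependency is not None:
        d = config.dependency
        si, ti = spec.items.index(d.source), spec.items.index(d.target)
        copy = rng.random(n) < d.rho
        resp[copy, ti] = np.minimum(resp[copy, si], spec.max_internal(d.target))

    import pandas as pd

    cov = pd.DataFrame({"age": ages, "group": groups})
    return ResponseMatrix(spec, resp, np.arange(n), cov)


def _focal_mask(dif: DIFSpec, groups: np.ndarray, ages: np.ndarray) -> np.ndarray:
    if dif.group_variable == "group":
        return groups == dif.focal_level
    raise ValueError(f"unknown DIF group variable {dif.group_variable!r}")


def inject_missingness(
    rm: ResponseMatrix,
    n_all_missing: int = 0,
    n_one: int = 0,
    n_two: int = 0,
    n_three: int = 0,
    n_missing_age: int = 0,
    seed: int = 0,
) -> ResponseMatrix:
    """Blank out responses/covariates for disjoint random persons by rule.

    Mirrors the exclusion structure of real survey data so the
    complete-case filter can be exercised: some persons answer no item at
    all, some miss exactly 1, 2 or 3 items, and some lack the age covariate.
    """
    from .data_model import MISSING

    rng = np.random.default_rng(seed)
    total = n_all_missing + n_one + n_two + n_three + n_missing_age
    if total > rm.n_persons:
        raise ValueError("more injected missingness than persons")
    chosen = rng.choice(rm.n_persons, size=total, replace=False)
    resp = rm.responses.copy()
    cov = rm.covariates.copy() if rm.covariates is not None else None
    pos = 0
    for count, k_missing in ((n_all_missing, rm.n_items), (n_one, 1), (n_two, 2), (n_three, 3)):
        for p in chosen[pos:pos + count]:
            cols = rng.choice(rm.n_items, size=k_missing, replace=False)
            resp[p, cols] = MISSING
        pos += count
    if n_missing_age:
        if cov is None or "age" not in cov.columns:
            raise ValueError("no age covariate to blank")
        cov.loc[chosen[pos:pos + n_missing_age], "age"] = np.nan
    return ResponseMatrix(rm.spec, resp, rm.person_ids.copy(), cov)
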