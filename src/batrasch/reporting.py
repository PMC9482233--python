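"""Burnout scoring, descriptives, targeting, and the end-to-end pipeline.

Burnout scores live on the questionnaire's external 1-5 scale: the total
score is the mean of all 23 item responses and each subscale score the
mean of its items. Descriptives report median and quartiles per scale and
per age group with a Mann-Whitney test for the group difference. Targeting
compares the person-location distribution with the item-threshold
distribution on the shared logit scale — for a well-targeted instrument
the person mean sits near the item mean of 0.

``run_pipeline`` orchestrates the full two-step construct validation:
item-level PCM fit with all diagnostics, then the testlet re-analysis with
variance decomposition, and writes a machine-readable JSON summary plus
per-stage CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .data_model import (
    ResponseMatrix,
    ScaleSpec,
    filter_complete_cases,
    load_responses,
    median_age_groups,
    split_random_samples,
)
from .dif_analysis import dif_anova
from .dimensionality import (
    pca_of_residuals,
    residual_correlations,
    smith_unidimensionality_test,
)
from .fit_diagnostics import (
    _intervals_of,
    fit_report,
    standardized_residuals,
    default_n_intervals,
)
from .pcm_core import (
    ItemParameters,
    PersonEstimates,
    estimate_item_parameters,
    estimate_person_locations,
)
from .testlet_analysis import (
    build_testlets,
    coefficient_alpha,
    collapse_unobserved_categories,
    latent_correlations,
    person_separation_index,
    variance_decomposition,
)

__all__ = [
    "BurnoutScores",
    "score_burnout",
    "descriptives",
    "targeting_summary",
    "run_pipeline",
    "analyse_sample",
]


@dataclasses.dataclass
class BurnoutScores:
    """Per-person mean scores on the external 1-5 scale."""

    total: np.ndarray
    subscale: dict[str, np.ndarray]


def score_burnout(rm: ResponseMatrix, spec: ScaleSpec | None = None) -> BurnoutScores:
    """Mean item response per person, overall and per subscale (external codes)."""
    spec = spec or rm.spec
    if rm.is_missing().any():
        raise ValueError("scoring requires complete responses")
    ext = rm.responses + spec.min_code
    sub = {}
    for s in spec.subscales:
        idx = [spec.items.index(i) for i in spec.items_of(s)]
        sub[s] = ext[:, idx].mean(axis=1)
    return BurnoutScores(total=ext.mean(axis=1), subscale=sub)


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear (type-7) interpolation: (1,2,3,4,5) -> Q1=2, median=3, Q3=4
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def descriptives(scores: BurnoutScores, groups: np.ndarray | None = None) -> pd.DataFrame:
    """Median/Q1/Q3/min/max per scale, per group and total, with
    Mann-Whitney p for the two-group difference (normal approximation,
    tie-corrected)."""
    scales = {"BAT-tot": scores.total, **scores.subscale}
    rows = []
    levels = []
    if groups is not None:
        groups = np.asarray(groups)
        levels = [g for g in ("younger", "older") if (groups == g).any()]
        levels = levels or list(pd.unique(groups))
    for name, vals in scales.items():
        for g in levels:
            x = vals[groups == g]
            med, q1, q3 = _quartiles(x)
            rows.append((name, g, len(x), med, q1, q3, float(x.min()), float(x.max()), np.nan))
        med, q1, q3 = _quartiles(vals)
        p = np.nan
        if len(levels) == 2:
            a = vals[groups == levels[0]]
            b = vals[groups == levels[1]]
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic").pvalue)
        rows.append((name, "total", len(vals), med, q1, q3,
                     float(vals.min()), float(vals.max()), p))
    return pd.DataFrame(
        rows, columns=["scale", "group", "n", "median", "q1", "q3", "min", "max",
                       "mannwhitney_p"],
    )


def targeting_summary(
    pe: PersonEstimates, ip: ItemParameters, bins: int | np.ndarray = 20
) -> dict:
    """Binned person and item-threshold distributions on the shared logit
    axis, with person mean/SD and the item mean (0 by the centring
    constraint) annotated."""
    ok = ~pe.extreme
    thresholds = ip.all_thresholds()
    lo = min(pe.theta[ok].min(), thresholds.min())
    hi = max(pe.theta[ok].max(), thresholds.max())
    edges = np.linspace(lo, hi, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    person_counts, _ = np.histogram(pe.theta[ok], bins=edges)
    item_counts, _ = np.histogram(thresholds, bins=edges)
    return {
        "bin_edges": edges,
        "person_counts": person_counts,
        "threshold_counts": item_counts,
        "person_mean": float(pe.theta[ok].mean()),
        "person_sd": float(pe.theta[ok].std(ddof=1)),
        "item_mean": float(np.mean([ip.item_location(i) for i in ip.items])),
        "n_extreme": int((~ok).sum()),
    }


def analyse_sample(
    rm: ResponseMatrix,
    groups: np.ndarray | None = None,
    n_intervals: int | None = None,
    alpha: float = 0.01,
    compute_dif: bool = True,
) -> dict:
    """One full Rasch analysis of a (complete-case) sample: fit, residual
    diagnostics, local dependency, Smith's test, PSI and alpha, optional
    DIF. Used for both the item-level and the testlet-level step."""
    rm2, collapse_map = collapse_unobserved_categories(rm)
    ip = estimate_item_parameters(rm2)
    pe = estimate_person_locations(rm2, ip)
    freport = fit_report(rm2, ip, pe, n_intervals=n_intervals, alpha=alpha)
    res = standardized_residuals(rm2, ip, pe)
    ld = residual_correlations(res, rm2)
    loadings = pca_of_residuals(res)
    smith = smith_unidimensionality_test(rm2, ip, loadings["PC1"], residuals=res)
    psi = person_separation_index(pe)
    alpha_coef = coefficient_alpha(rm2.responses)
    dif = None
    if compute_dif and groups is not None:
        g = n_intervals or default_n_intervals(int((~pe.extreme).sum()))
        intervals = _intervals_of(pe.theta[~pe.extreme], g)
        dif = dif_anova(res, np.asarray(groups)[~pe.extreme], intervals, alpha=alpha)
    collapsed = {k: v for k, v in collapse_map.items()
                 if (np.diff(v) == 0).any() or v[0] != 0}
    return {
        "item_parameters": ip,
        "person_estimates": pe,
        "fit_report": freport,
        "local_dependency": ld,
        "pca_loadings": loadings,
        "smith": smith,
        "psi": psi,
        "alpha": alpha_coef,
        "dif": dif,
        "collapsed_categories": collapsed,
        "targeting": targeting_summary(pe, ip),
    }


def _overall_block(a: dict) -> dict:
    s = a["fit_report"].summary
    return {
        "item_fit_mean": round(s["item_fit_mean"], 2),
        "item_fit_sd": round(s["item_fit_sd"], 2),
        "person_fit_mean": round(s["person_fit_mean"], 2),
        "person_fit_sd": round(s["person_fit_sd"], 2),
        "chi2": round(s["total_chi2"], 2),
        "chi2_df": s["total_df"],
        "chi2_p": round(s["total_p"], 4),
        "psi": round(a["psi"], 2),
        "smith_pct": round(a["smith"].proportion_pct, 2),
        "smith_ci": [round(c, 2) for c in a["smith"].ci_pct],
        "smith_unidimensional": a["smith"].unidimensional,
        "alpha": round(a["alpha"], 2),
        "n_ld_flags": len(a["local_dependency"].flagged_pairs),
        "n_ld_within": sum(1 for f in a["local_dependency"].flagged_pairs
                           if f[3] == "within"),
    }


def run_pipeline(
    rm: ResponseMatrix | None = None,
    csv_path: str | Path | None = None,
    spec: ScaleSpec | None = None,
    outdir: str | Path = "batrasch_report",
    seed: int = 0,
    sample_sizes: list[int] | None = None,
    required_covariates: list[str] = ("age",),
    alpha: float = 0.01,
) -> dict:
    """Run the full two-step construct validation and write the report.

    Steps: load -> complete-case filter -> optional random-sample split ->
    item-level PCM analysis (fit, LD, Smith, DIF by median-age group) ->
    testlet re-analysis -> variance decomposition and latent correlations
    -> burnout descriptives -> targeting. Outputs a JSON summary and CSV
    tables under ``outdir``; identical config + seed gives byte-identical
    JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if rm is None:
            rm = load_responses(csv_path, spec)
        stage = "filter"
        rm_cc, excl = filter_complete_cases(rm, list(required_covariates))
        stage = "split"
        if sample_sizes:
            sample = split_random_samples(rm_cc, list(sample_sizes), seed)[0]
        else:
            sample = rm_cc
        groups = None
        if sample.covariates is not None and "age" in sample.covariates.columns:
            groups, cut = median_age_groups(sample.covariates["age"].to_numpy())
        stage = "item_level_analysis"
        item_level = analyse_sample(sample, groups=groups, alpha=alpha)
        stage = "testlet_analysis"
        testlets = build_testlets(sample)
        testlet_level = analyse_sample(testlets, groups=groups, alpha=alpha,
                                       compute_dif=False)
        stage = "variance_decomposition"
        decomp = variance_decomposition(item_level["alpha"], testlet_level["alpha"])
        latent = latent_correlations(sample)
        stage = "descriptives"
        scores = score_burnout(sample)
        desc = descriptives(scores, groups)
        stage = "write"
        summary = {
            "version": __version__,
            "seed": seed,
            "n_input": rm.n_persons,
            "exclusions": {
                "all_missing": excl.all_missing,
                "missing_by_count": excl.missing_by_count,
                "missing_covariate": excl.missing_covariate,
                "n_retained": excl.n_retained,
            },
            "n_analysed": sample.n_persons,
            "item_level": _overall_block(item_level),
            "testlet_level": _overall_block(testlet_level),
            "variance_decomposition": {k: round(v, 4) for k, v in decomp.items()},
            "average_disattenuated_latent_correlation":
                round(latent["average_disattenuated"], 4),
            "subscale_psi": {k: round(v, 4) for k, v in latent["psi"].items()},
            "targeting": {
                "person_mean": round(item_level["targeting"]["person_mean"], 2) + 0.0,
                "person_sd": round(item_level["targeting"]["person_sd"], 2) + 0.0,
                "item_mean": round(item_level["targeting"]["item_mean"], 2) + 0.0,
            },
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        _write_tables(outdir, item_level, testlet_level, desc)
        return {
            "summary": summary,
            "item_level": item_level,
            "testlet_level": testlet_level,
            "descriptives": desc,
            "exclusions": excl,
        }
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e


def _item_table(a: dict) -> pd.DataFrame:
    ip = a["item_parameters"]
    rows = []
    for item in ip.items:
        row = {"item": item, "fit_residual":
               round(float(a["fit_report"].item_table.loc[item, "fit_residual"]), 2)}
        for k, (d, s) in enumerate(zip(ip.thresholds[item], ip.se[item]), start=1):
            row[f"threshold_{k}"] = round(float(d), 2)
            row[f"se_{k}"] = round(float(s), 3)
        row["ordered"] = bool(a["fit_report"].item_table.loc[item, "ordered"])
        row["chi2"] = round(float(a["fit_report"].item_table.loc[item, "chi2"]), 2)
        row["p"] = round(float(a["fit_report"].item_table.loc[item, "p"]), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tables(outdir: Path, item_level: dict, testlet_level: dict,
                  desc: pd.DataFrame) -> None:
    _item_table(item_level).to_csv(outdir / "item_fit.csv", index=False)
    _item_table(testlet_level).to_csv(outdir / "testlet_fit.csv", index=False)
    item_level["local_dependency"].corr.round(3).to_csv(outdir / "residual_correlations.csv")
    if item_level["dif"] is not None:
        item_level["dif"].table.round(4).to_csv(outdir / "dif.csv")
    desc.round(2).to_csv(outdir / "descriptives.csv", index=False)
    t = item_level["targeting"]
    pd.DataFrame({
        "bin_left": t["bin_edges"][:-1], "bin_right": t["bin_edges"][1:],
        "person_count": t["person_counts"], "threshold_count": t["threshold_counts"],
    }).to_csv(outdir / "targeting_bins.csv", index=False)
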