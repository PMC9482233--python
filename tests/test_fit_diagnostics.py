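import numpy as np
import pandas as pd
import pytest

from batrasch import (
    assign_class_intervals,
    default_bat_config,
    estimate_item_parameters,
    estimate_person_locations,
    fit_report,
    fit_residuals,
    generate,
    item_chi_square,
    salzberger_threshold_test,
    standardized_residuals,
    threshold_order_check,
)
from batrasch.fit_diagnostics import ResidualMatrix, _intervals_of
from batrasch.pcm_core import ItemParameters, PersonEstimates
from batrasch.testlet_analysis import collapse_unobserved_categories


@pytest.fixture(scope="module")
def null_fit(null_cohort):
    rm, _ = collapse_unobserved_categories(null_cohort)
    ip = estimate_item_parameters(rm, compute_se=False)
    pe = estimate_person_locations(rm, ip)
    res = standardized_residuals(rm, ip, pe)
    return rm, ip, pe, res


class TestStandardizedResiduals:
    def test_observed_equals_expected_gives_zero(self):
        # dichotomous item at theta = delta: E[x] = 0.5, V = 0.25
        # so x=1 gives z = +1 and x=0 gives z = -1
        ip = ItemParameters(("d", "e"), {"d": np.array([0.0]), "e": np.array([0.0])},
                            {"d": np.zeros(1), "e": np.zeros(1)})
        from batrasch.data_model import ScaleSpec, ResponseMatrix

        spec = ScaleSpec(items=("d", "e"), subscale_of={"d": "S", "e": "S"},
                         n_categories={"d": 2, "e": 2}, min_code=0, max_code=1)
        rm = ResponseMatrix(spec, np.array([[1, 0], [0, 1]]), np.arange(2))
        pe = PersonEstimates(np.arange(2), np.array([1, 1]),
                             np.array([0.0, 0.0]), np.array([1.0, 1.0]),
                             np.array([False, False]))
        res = standardized_residuals(rm, ip, pe)
        assert np.allclose(np.abs(res.z), 1.0)
        assert res.z[0, 0] == pytest.approx(1.0)

    def test_item_means_of_residuals_near_zero_on_null_data(self, null_fit):
        *_, res = null_fit
        assert np.abs(res.z.mean(axis=0)).max() < 0.15


class TestFitResiduals:
    def test_zero_residuals_hit_the_guttman_floor(self, null_fit):
        *_, res = null_fit
        perfect = ResidualMatrix(
            res.items, np.zeros_like(res.z), res.person_rows, res.theta,
            res.ez2, res.vz2, res.ez2_lin, res.vz2_lin, res.var_correction,
        )
        item_fr, person_fr = fit_residuals(perfect)
        real_fr, _ = fit_residuals(res)
        assert (item_fr < real_fr).all()
        assert (item_fr < -2.5).all()

    def test_null_calibration_mean_and_spread(self, null_fit):
        *_, res = null_fit
        item_fr, person_fr = fit_residuals(res)
        assert abs(item_fr.mean()) < 0.45
        assert 0.5 < item_fr.std(ddof=1) < 1.5
        assert abs(person_fr.mean()) < 0.2
        assert 0.8 < person_fr.std(ddof=1) < 1.25

    def test_overdiscriminating_item_strongly_negative(self):
        # double the slope of EX6 relative to the common trait
        from batrasch.pcm_core import category_probabilities
        from batrasch.data_model import ResponseMatrix

        cfg = default_bat_config(n_persons=800, seed=21)
        rng = np.random.default_rng(21)
        theta = cfg.person_mean + cfg.person_sd * rng.standard_normal(800)
        resp = np.empty((800, 23), dtype=int)
        for j, item in enumerate(cfg.spec.items):
            t = theta if item != "EX6" else cfg.person_mean + 2.0 * (theta - cfg.person_mean)
            p = category_probabilities(t, cfg.item_thresholds[item])
            resp[:, j] = (p.cumsum(axis=1) < rng.random(800)[:, None]).sum(axis=1)
        rm = ResponseMatrix(cfg.spec, resp, np.arange(800))
        rm, _ = collapse_unobserved_categories(rm)
        ip = estimate_item_parameters(rm, compute_se=False)
        pe = estimate_person_locations(rm, ip)
        rep = fit_report(rm, ip, pe)
        assert rep.item_table.loc["EX6", "fit_residual"] < -2.5
        assert rep.item_table.loc["EX6", "significant"]


class TestClassIntervals:
    def test_near_equal_interval_sizes(self, null_fit):
        _, _, pe, _ = null_fit
        labels = assign_class_intervals(pe, 8)
        counts = np.bincount(labels)
        assert len(counts) == 8
        # equal-count cuts up to tie blocks: theta-hat is discrete in the raw
        # score, so whole score groups move between intervals together
        theta = pe.theta[~pe.extreme]
        max_tie = max(np.bincount(np.unique(theta, return_inverse=True)[1]))
        assert counts.max() - counts.min() <= 2 * max_tie
        assert counts.min() > 0

    def test_interval_means_increase(self, null_fit):
        _, _, pe, res = null_fit
        labels = assign_class_intervals(pe, 6)
        means = [res.theta[labels == c].mean() for c in range(6)]
        assert np.all(np.diff(means) > 0)

    def test_identical_locations_cannot_form_intervals(self):
        with pytest.raises(ValueError):
            _intervals_of(np.ones(100), 2)


class TestItemChiSquare:
    def test_zero_residuals_give_zero_chi_square(self, null_fit):
        *_, res = null_fit
        zero = ResidualMatrix(
            res.items, np.zeros_like(res.z), res.person_rows, res.theta,
            res.ez2, res.vz2, res.ez2_lin, res.vz2_lin, res.var_correction,
        )
        labels = _intervals_of(res.theta, 5)
        tab = item_chi_square(zero, labels)
        assert np.allclose(tab["chi2"], 0)
        assert np.allclose(tab["p"], 1)
        assert (tab["df"] == 4).all()

    def test_null_overall_test_not_significant(self, null_fit):
        rm, ip, pe, _ = null_fit
        rep = fit_report(rm, ip, pe)
        assert rep.summary["total_p"] > 0.01
        assert rep.summary["total_chi2"] == pytest.approx(
            rep.item_table["chi2"].sum()
        )


class TestThresholdOrdering:
    def test_reversed_pair_flagged_with_location(self):
        ip = ItemParameters(
            ("CI5", "EX1"),
            {"CI5": np.array([-2.65, 0.95, 3.71, 1.99]),
             "EX1": np.array([-4.61, -2.21, -0.59, 2.20])},
            {"CI5": np.ones(4), "EX1": np.ones(4)},
        )
        tab = threshold_order_check(ip)
        assert not tab.loc["CI5", "ordered"]
        assert tab.loc["CI5", "disordered_pair"] == (3, 4)
        assert tab.loc["EX1", "ordered"]

    def test_strictly_increasing_is_ordered(self):
        ip = ItemParameters(("x",), {"x": np.array([-1.0, 0.0, 2.0])},
                            {"x": np.ones(3)})
        assert threshold_order_check(ip).loc["x", "ordered"]


class TestSalzberger:
    def test_overwhelming_separation_is_ordered(self):
        out = salzberger_threshold_test(0.0, 0.1, 3.0, 0.1, alpha=0.01)
        assert out["verdict"] == "ordered"
        assert out["z"] == pytest.approx(21.2, abs=0.05)

    def test_reversed_but_noisy_pair_undecided(self):
        # the classic reversed pair: estimates 3.71 and 1.99 with SEs
        # 0.924 and 1.428 cannot establish true disordering
        out = salzberger_threshold_test(3.71, 0.924, 1.99, 1.428, alpha=0.01)
        assert out["verdict"] == "undecided"
        assert abs(out["z"]) == pytest.approx(1.01, abs=0.01)

    def test_equal_thresholds_undecided(self):
        assert salzberger_threshold_test(1.0, 0.3, 1.0, 0.4)["verdict"] == "undecided"

    def test_strong_reversal_is_disordered(self):
        assert salzberger_threshold_test(2.0, 0.05, 0.0, 0.05)["verdict"] == "disordered"

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            salzberger_threshold_test(0.0, 0.0, 1.0, 0.1)
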