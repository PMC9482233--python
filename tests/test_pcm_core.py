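import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import logsumexp

from batrasch import (
    category_probabilities,
    elementary_symmetric_functions,
    estimate_item_parameters,
    estimate_person_locations,
    expected_score_and_variance,
    default_bat_config,
    generate,
)
from batrasch.data_model import ResponseMatrix, ScaleSpec
from batrasch.pcm_core import NullCategoryError, _center
from batrasch.synthetic_data import GeneratorConfig

from conftest import make_matrix


def brute_esf(thresholds_list):
    """Oracle: elementary symmetric functions by exhaustive enumeration."""
    R = sum(len(t) for t in thresholds_list)
    out = np.zeros(R + 1)
    for pat in itertools.product(*[range(len(t) + 1) for t in thresholds_list]):
        w = np.prod([np.exp(-np.sum(t[:x])) for x, t in zip(pat, thresholds_list)])
        out[sum(pat)] += w
    return out


def brute_cml(responses, m_list):
    """Oracle: maximize the conditional likelihood over enumerated patterns."""
    patterns = np.array(list(itertools.product(*[range(m + 1) for m in m_list])))
    pattern_totals = patterns.sum(axis=1)
    totals = responses.sum(axis=1)
    interior = (totals > 0) & (totals < sum(m_list))
    resp = responses[interior]
    r_obs = totals[interior]

    def negll(delta):
        betas = []
        pos = 0
        for m in m_list:
            betas.append(np.concatenate([[0.0], np.cumsum(delta[pos:pos + m])]))
            pos += m
        logw = np.array(
            [-sum(b[x] for b, x in zip(betas, pat)) for pat in patterns]
        )
        log_gamma = {
            r: logsumexp(logw[pattern_totals == r])
            for r in np.unique(pattern_totals)
        }
        ll = 0.0
        for row, r in zip(resp, r_obs):
            ll += -sum(b[x] for b, x in zip(betas, row)) - log_gamma[r]
        return -ll

    res = minimize(negll, np.zeros(sum(m_list)), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return _center(res.x, m_list)


class TestCategoryProbabilities:
    def test_dichotomous_at_threshold_is_half(self):
        p = category_probabilities(0.0, np.array([0.0]))
        assert np.allclose(p, [0.5, 0.5])

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_adjacent_categories_equiprobable_at_threshold(self, k):
        th = np.array([-1.0, 0.0, 1.0, 2.0])
        p = category_probabilities(th[k], th)
        assert p[k] == pytest.approx(p[k + 1], rel=1e-12)

    def test_matches_closed_form_evaluation(self):
        # direct evaluation of P(x) = exp(x*theta - beta_x)/sum at theta=1
        th = np.array([-1.0, 0.0, 1.0, 2.0])
        beta = np.concatenate([[0.0], np.cumsum(th)])
        raw = np.exp(np.arange(5) * 1.0 - beta)
        assert np.allclose(category_probabilities(1.0, th), raw / raw.sum())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        theta=st.floats(-6, 6),
        th=st.lists(st.floats(-4, 4), min_size=1, max_size=5),
    )
    def test_probabilities_positive_and_sum_to_one(self, theta, th):
        p = category_probabilities(theta, np.array(th))
        assert (p > 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestExpectedScore:
    def test_symmetric_item_has_midpoint_expectation_at_zero(self):
        e, v = expected_score_and_variance(0.0, np.array([-1.0, 1.0]))
        assert e == pytest.approx(1.0)
        assert v > 0

    def test_limit_is_max_score(self):
        e, _ = expected_score_and_variance(40.0, np.array([-1.0, 0.0, 1.0, 2.0]))
        assert e == pytest.approx(4.0, abs=1e-8)

    def test_matches_summation_oracle(self):
        th = np.array([-1.0, 0.0, 1.0, 2.0])
        p = category_probabilities(0.5, th)
        x = np.arange(5)
        e, v = expected_score_and_variance(0.5, th)
        assert e == pytest.approx(np.sum(x * p))
        assert v == pytest.approx(np.sum(x ** 2 * p) - np.sum(x * p) ** 2)

    def test_expectation_increases_with_theta(self):
        th = np.array([0.3, -0.2, 1.4])  # disordered thresholds included
        thetas = np.linspace(-5, 5, 81)
        e = [expected_score_and_variance(t, th)[0] for t in thetas]
        assert np.all(np.diff(e) > 0)


class TestElementarySymmetricFunctions:
    def test_single_dichotomous_item(self):
        assert np.allclose(elementary_symmetric_functions([np.array([0.0])]), [1, 1])

    def test_two_dichotomous_items_binomial(self):
        g = elementary_symmetric_functions([np.array([0.0]), np.array([0.0])])
        assert np.allclose(g, [1, 2, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(-2, 2), min_size=1, max_size=3),
            min_size=1, max_size=4,
        )
    )
    def test_recursion_equals_enumeration(self, raw):
        ths = [np.array(t) for t in raw]
        g = elementary_symmetric_functions(ths)
        assert np.allclose(g, brute_esf(ths), rtol=1e-10)


class TestItemEstimation:
    def test_cml_matches_brute_force_maximizer(self, toy_spec):
        rng = np.random.default_rng(3)
        gen = [np.array([-0.8, 0.4]), np.array([0.0, 1.0]), np.array([-0.5, -0.1])]
        theta = rng.normal(0, 1, 200)
        resp = np.empty((200, 3), dtype=int)
        for j, t in enumerate(gen):
            p = category_probabilities(theta, t)
            resp[:, j] = (p.cumsum(axis=1) < rng.random(200)[:, None]).sum(axis=1)
        rm = make_matrix(toy_spec, resp)
        ip = estimate_item_parameters(rm, compute_se=False)
        est = np.concatenate([ip.thresholds[i] for i in toy_spec.items])
        oracle = brute_cml(resp, [2, 2, 2])
        assert np.allclose(est, oracle, atol=1e-5)

    def test_identical_margins_give_symmetric_centred_estimates(self):
        spec = ScaleSpec(
            items=("p", "q"), subscale_of={"p": "S", "q": "S"},
            n_categories={"p": 2, "q": 2}, min_code=0, max_code=1,
        )
        resp = np.array([[0, 1], [1, 0]] * 40 + [[1, 1], [0, 0]] * 10)
        ip = estimate_item_parameters(make_matrix(spec, resp), compute_se=False)
        assert ip.thresholds["p"][0] == pytest.approx(ip.thresholds["q"][0], abs=1e-8)
        assert ip.thresholds["p"][0] + ip.thresholds["q"][0] == pytest.approx(0, abs=1e-10)

    def test_null_category_error_names_item_and_category(self, toy_spec):
        # item "a" never reaches its top category
        resp = np.array(
            [[0, 1, 2], [1, 1, 1], [1, 1, 0], [1, 2, 0], [0, 0, 2], [1, 2, 1]]
        )
        with pytest.raises(NullCategoryError, match=r"category 2 .*'a'"):
            estimate_item_parameters(make_matrix(toy_spec, resp))

    def test_invariance_across_person_distributions(self, toy_spec):
        # thresholds recovered from two very different cohorts agree
        gen = [np.array([-0.8, 0.4]), np.array([0.0, 1.0]), np.array([-0.5, -0.1])]
        ests = []
        for seed, (mu, sd) in ((1, (-1.0, 0.6)), (2, (0.5, 1.0))):
            rng = np.random.default_rng(seed)
            theta = rng.normal(mu, sd, 4000)
            resp = np.empty((4000, 3), dtype=int)
            for j, t in enumerate(gen):
                p = category_probabilities(theta, t)
                resp[:, j] = (p.cumsum(axis=1) < rng.random(4000)[:, None]).sum(axis=1)
            ip = estimate_item_parameters(make_matrix(toy_spec, resp))
            ests.append(ip)
        for item in toy_spec.items:
            d = ests[0].thresholds[item] - ests[1].thresholds[item]
            joint_se = np.sqrt(ests[0].se[item] ** 2 + ests[1].se[item] ** 2)
            assert (np.abs(d) < 3 * joint_se).all()


@pytest.fixture(scope="module")
def fitted(null_cohort):
    from batrasch.testlet_analysis import collapse_unobserved_categories

    rm, _ = collapse_unobserved_categories(null_cohort)
    ip = estimate_item_parameters(rm, compute_se=False)
    return rm, ip, estimate_person_locations(rm, ip)


class TestPersonEstimation:

    def test_equal_raw_scores_give_identical_estimates(self, fitted):
        _, _, pe = fitted
        for r in np.unique(pe.raw_scores)[:10]:
            sel = pe.raw_scores == r
            assert np.ptp(pe.theta[sel]) == 0
            assert np.ptp(pe.se[sel]) == 0

    def test_theta_strictly_increasing_in_raw_score(self, fitted):
        _, _, pe = fitted
        scores = np.unique(pe.raw_scores)
        order = np.argsort(scores)
        th = np.array([pe.theta[pe.raw_scores == r][0] for r in scores[order]])
        assert np.all(np.diff(th) > 0)

    def test_extreme_flag_matches_score_bounds(self, fitted):
        rm, ip, pe = fitted
        max_total = ip.total_max()
        assert np.array_equal(
            pe.extreme, (pe.raw_scores == 0) | (pe.raw_scores == max_total)
        )

    def test_symmetric_instrument_mid_score_maps_to_zero(self, toy_spec):
        gen = {"a": np.array([-1.0, 1.0]), "b": np.array([-0.5, 0.5]),
               "c": np.array([-2.0, 2.0])}
        from batrasch.pcm_core import ItemParameters

        ip = ItemParameters(("a", "b", "c"), gen, {k: np.zeros(2) for k in gen})
        resp = np.array([[1, 1, 1], [0, 1, 2]])
        pe = estimate_person_locations(make_matrix(toy_spec, resp), ip)
        assert pe.theta[0] == pytest.approx(0.0, abs=1e-8)
        assert pe.theta[1] == pytest.approx(0.0, abs=1e-8)  # same raw score

    def test_recovers_generating_person_mean(self):
        # estimate persons at the generating item parameters
        from batrasch.pcm_core import ItemParameters

        cfg = default_bat_config(n_persons=800, seed=17)
        rm = generate(cfg)
        ip = ItemParameters(
            tuple(rm.spec.items),
            {k: np.asarray(v, float) for k, v in cfg.item_thresholds.items()},
            {k: np.zeros(4) for k in cfg.item_thresholds},
        )
        pe = estimate_person_locations(rm, ip)
        ok = ~pe.extreme
        mean = pe.theta[ok].mean()
        sem = pe.theta[ok].std(ddof=1) / np.sqrt(ok.sum())
        assert abs(mean - (-0.95)) < 3 * sem + 0.03  # small ML-bias allowance
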