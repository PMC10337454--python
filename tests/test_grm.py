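"""Graded response model: probabilities, information, EAP, EM calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gradedcat as gc
from gradedcat.bank import InvalidInputError

# random-but-valid item generator for property tests
item_strategy = st.builds(
    lambda a, b0, gaps: gc.ItemParameters(
        "it", a, tuple(np.cumsum([b0] + [g + 0.05 for g in gaps]))
    ),
    a=st.floats(0.2, 4.0),
    b0=st.floats(-3.0, 3.0),
    gaps=st.lists(st.floats(0.0, 2.0), min_size=1, max_size=4),
)


class TestCategoryProbabilities:
    def test_hand_computed_logistic_values(self):
        item = gc.ItemParameters("x", 1.0, (-1.0, 0.0, 1.0))
        p = gc.category_probabilities(item, 0.0)
        np.testing.assert_allclose(
            p, [0.26894142, 0.23105858, 0.23105858, 0.26894142], atol=1e-8
        )

    def test_symmetric_item_gives_palindromic_vector(self):
        item = gc.ItemParameters("x", 1.7, (-1.5, 0.0, 1.5))
        p = gc.category_probabilities(item, 0.0)
        np.testing.assert_allclose(p, p[::-1], atol=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(item=item_strategy, theta=st.floats(-5.0, 5.0))
    def test_probability_axioms(self, item, theta):
        p = gc.category_probabilities(item, theta)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-10
        # cumulative curves non-increasing in category index
        cum = np.cumsum(p[::-1])[::-1]  # P(X >= k)
        assert np.all(np.diff(cum) <= 1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(item=item_strategy)
    def test_expected_score_monotone_in_theta(self, item):
        grid = np.linspace(-5, 5, 41)
        p = gc.category_probabilities(item, grid)
        escore = p @ np.arange(p.shape[1])
        assert np.all(np.diff(escore) >= -1e-10)

    def test_nonfinite_theta_rejected(self):
        item = gc.ItemParameters("x", 1.0, (0.0,))
        with pytest.raises(InvalidInputError):
            gc.category_probabilities(item, np.inf)


class TestInformation:
    def test_zero_discrimination_no_information(self):
        item = gc.ItemParameters("x", 0.0, (-1.0, 0.0, 1.0))
        assert gc.item_information(item, 0.0) == 0.0
        assert gc.item_information(item, 2.5) == 0.0

    def test_dichotomous_closed_form_at_threshold(self):
        # two-category item reduces to a^2 P (1-P) = 4 * 0.25 at theta = b
        item = gc.ItemParameters("x", 2.0, (0.7,))
        assert gc.item_information(item, 0.7) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("theta", [-2.0, -0.3, 0.0, 1.1, 2.4])
    def test_matches_finite_difference_expected_curvature(self, theta):
        # Fisher information = -E[d^2 log P_k / d theta^2], by central differences
        item = gc.ItemParameters("x", 1.6, (-0.8, 0.2, 1.3))
        h = 1e-4
        logp = lambda t: np.log(gc.category_probabilities(item, t))
        curv = -(logp(theta + h) - 2 * logp(theta) + logp(theta - h)) / h**2
        expected = float(gc.category_probabilities(item, theta) @ curv)
        assert gc.item_information(item, theta) == pytest.approx(expected, abs=1e-4)

    def test_information_vanishes_in_the_tails(self):
        item = gc.ItemParameters("x", 1.5, (-1.0, 0.0, 1.0))
        assert gc.item_information(item, 12.0) < 1e-4
        assert gc.item_information(item, -12.0) < 1e-4


class TestTestInformationAndSem:
    def test_sem_is_inverse_root_information(self, strong_bank):
        info, sem = gc.test_information_and_sem(strong_bank, 0.5)
        assert sem == pytest.approx(info ** -0.5)

    def test_adding_an_item_never_decreases_information(self, strong_bank):
        items = list(strong_bank.items)
        grid = np.linspace(-4, 4, 33)
        info_small, _ = gc.test_information_and_sem(items[:-1], grid)
        info_full, _ = gc.test_information_and_sem(items, grid)
        assert np.all(info_full >= info_small)

    def test_zero_information_gives_infinite_sem(self):
        item = gc.ItemParameters("x", 0.0, (0.0,))
        _info, sem = gc.test_information_and_sem([item], 0.0)
        assert np.isinf(sem)

    def test_peaked_bank_peaks_above_zero(self, peaked_bank):
        # all thresholds >= 0, so a grid search should peak at positive theta
        grid = np.linspace(-4, 4, 801)
        info, _ = gc.test_information_and_sem(peaked_bank, grid)
        assert grid[int(np.argmax(info))] > 0


class TestReliabilitySemMap:
    @pytest.mark.parametrize(
        "reliability,expected",
        [(1.0, 0.0), (0.9, 0.3162), (0.8, 0.4472), (0.7, 0.5477), (0.6, 0.6325), (0.5, 0.7071)],
    )
    def test_printed_correspondence(self, reliability, expected):
        assert gc.reliability_sem_conversion(reliability) == pytest.approx(expected, abs=5e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 1.0))
    def test_round_trip_identity(self, reliability):
        sem = gc.reliability_sem_conversion(reliability)
        assert gc.sem_to_reliability(sem) == pytest.approx(reliability, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            gc.reliability_sem_conversion(bad)


class TestEapScore:
    def test_empty_pattern_returns_prior_moments(self, strong_bank):
        est = gc.eap_score(strong_bank, {})
        assert est.theta == pytest.approx(0.0, abs=1e-3)
        assert est.se == pytest.approx(1.0, abs=1e-3)
        assert est.n_items_used == 0

    def test_symmetric_item_antisymmetric_estimates(self):
        item = gc.ItemParameters("x", 1.0, (-1.0, 0.0, 1.0))
        top = gc.eap_score([item], {"x": 3})
        bottom = gc.eap_score([item], {"x": 0})
        assert top.theta == pytest.approx(-bottom.theta, abs=1e-10)

    def _dense_oracle(self, items, responses, n_points=10_001):
        theta = np.linspace(-8, 8, n_points)
        logpost = -0.5 * theta**2
        for it, cat in responses:
            logpost += np.log(gc.category_probabilities(it, theta)[:, cat])
        post = np.exp(logpost - logpost.max())
        post /= post.sum()
        mean = post @ theta
        return mean, np.sqrt(post @ (theta - mean) ** 2)

    def test_single_item_matches_dense_grid_oracle(self):
        item = gc.ItemParameters("x", 1.5, (-0.5, 0.5, 1.5))
        est = gc.eap_score([item], {"x": 3})
        mean, sd = self._dense_oracle([item], [(item, 3)])
        assert est.theta == pytest.approx(mean, abs=1e-3)
        assert est.se == pytest.approx(sd, abs=1e-3)

    def test_multi_item_patterns_match_dense_grid_oracle(self, strong_bank):
        rng = np.random.default_rng(3)
        items = strong_bank.items
        for _ in range(5):
            pattern = {it.id: int(rng.integers(0, 4)) for it in items}
            est = gc.eap_score(items, pattern)
            mean, _sd = self._dense_oracle(items, [(it, pattern[it.id]) for it in items])
            assert est.theta == pytest.approx(mean, abs=1e-3)

    def test_out_of_range_category_rejected(self, strong_bank):
        with pytest.raises(InvalidInputError):
            gc.eap_score(strong_bank, {"s1": 4})

    def test_matrix_scoring_agrees_with_single_patterns(self, strong_bank):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 4, size=(6, 7))
        theta, se = gc.eap_score_matrix(strong_bank, x)
        for row in range(6):
            est = gc.eap_score(strong_bank, dict(zip(strong_bank.item_ids, x[row])))
            assert theta[row] == pytest.approx(est.theta, abs=1e-12)
            assert se[row] == pytest.approx(est.se, abs=1e-12)


class TestCalibration:
    def test_parameter_recovery_on_known_bank(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        sub = bank.subset("depression")
        result = gc.calibrate_grm(matrix, scale="depression", bank=bank, se_method="xpd")
        a_true = np.array([it.a for it in sub.items])
        a_est = np.array([it.a for it in result.bank.items])
        b_true = np.concatenate([it.b for it in sub.items])
        b_est = np.concatenate([it.b for it in result.bank.items])
        assert np.sqrt(np.mean((a_true - a_est) ** 2)) < 0.2
        assert np.sqrt(np.mean((b_true - b_est) ** 2)) < 0.15
        assert result.converged

    def test_em_loglikelihood_monotone(self, depression_calibration):
        _bank, _matrix, result = depression_calibration
        trace = np.asarray(result.ll_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_estimated_thresholds_ordered(self, depression_calibration):
        _bank, _matrix, result = depression_calibration
        for it in result.bank.items:
            assert np.all(np.diff(it.b) > 0)

    def test_standard_errors_positive_and_plausible(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        result = gc.calibrate_grm(matrix, scale="anxiety", bank=bank, se_method="xpd")
        for item_se in result.standard_errors.values():
            assert item_se["a"] > 0
            assert all(se > 0 for se in item_se["b"])
            assert item_se["a"] < 1.0  # n=2000 should pin a well below that

    def test_never_observed_top_category_collapsed(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        ids = bank.scales["depression"]
        clipped = matrix.data[ids].clip(upper=2)
        result = gc.calibrate_grm(clipped, se_method="none")
        assert all(len(it.b) == 2 for it in result.bank.items)
        assert set(result.category_collapse_map) == set()  # 0,1,2 already contiguous

    def test_collapse_map_recorded_for_gap_categories(self):
        rng = np.random.default_rng(8)
        x = rng.choice([0, 1, 3], size=(400, 3), p=[0.4, 0.3, 0.3])
        result = gc.calibrate_grm(x, se_method="none")
        assert all(m == {0: 0, 1: 1, 3: 2} for m in result.category_collapse_map.values())

    def test_degenerate_item_named_in_error(self):
        x = np.column_stack([np.zeros(100, dtype=int), np.random.default_rng(0).integers(0, 4, 100)])
        with pytest.raises(InvalidInputError, match="item1"):
            gc.calibrate_grm(x, se_method="none")

    def test_recovery_improves_with_sample_size(self):
        cfg_small = gc.GenerationConfig(n_respondents=500, n_scales=1, seed=21)
        cfg_large = gc.GenerationConfig(n_respondents=4000, n_scales=1, seed=21)
        rmses = {}
        for label, cfg in [("small", cfg_small), ("large", cfg_large)]:
            bank, _t, matrix = gc.generate_dataset(cfg)
            res = gc.calibrate_grm(matrix, se_method="none")
            a_true = np.array([it.a for it in bank.items])
            a_est = np.array([it.a for it in res.bank.items])
            b_true = np.concatenate([it.b for it in bank.items])
            b_est = np.concatenate([it.b for it in res.bank.items])
            rmses[label] = np.sqrt(np.mean((np.concatenate([a_true - a_est, b_true - b_est])) ** 2))
        assert rmses["large"] < rmses["small"]


class TestMarginalReliability:
    def test_information_rich_limit(self):
        # strong items whose thresholds tile the prior bulk: near-perfect scale
        cuts = np.linspace(-2.7, 2.7, 21)
        items = [
            gc.ItemParameters(f"i{k}", 10.0, tuple(cuts[3 * k : 3 * k + 3]))
            for k in range(7)
        ]
        assert gc.marginal_reliability(items) > 0.95

    def test_no_information_limit(self):
        item = gc.ItemParameters("x", 1e-4, (-1.0, 0.0, 1.0))
        assert gc.marginal_reliability([item]) == pytest.approx(0.0, abs=1e-3)

    def test_bounded_in_unit_interval(self, strong_bank, peaked_bank):
        for bank in (strong_bank, peaked_bank):
            rel = gc.marginal_reliability(bank)
            assert 0.0 <= rel < 1.0

    def test_matches_monte_carlo_eap_posterior_variance(self, strong_bank):
        # oracle: 1 - mean EAP posterior variance over 50,000 simulated traits
        rng = np.random.default_rng(12)
        theta = rng.normal(size=50_000)
        matrix = gc.simulate_responses(strong_bank, theta, seed=13)
        _est, se = gc.eap_score_matrix(strong_bank, matrix.values())
        mc = 1.0 - np.mean(se**2)
        assert gc.marginal_reliability(strong_bank) == pytest.approx(mc, abs=0.02)


class TestThresholdOrdering:
    def test_well_separated_item_is_ordered(self):
        item = gc.ItemParameters("x", 2.0, (-1.0, 0.0, 1.0))
        (report,) = gc.check_threshold_ordering([item])
        assert report["ordered"] and report["non_modal_categories"] == []

    def test_cramped_thresholds_flag_intermediate_categories(self):
        item = gc.ItemParameters("x", 0.5, (-0.05, 0.0, 0.05))
        (report,) = gc.check_threshold_ordering([item])
        assert not report["ordered"]
        assert report["non_modal_categories"] == [1, 2]

    def test_one_report_entry_per_item(self, strong_bank):
        report = gc.check_threshold_ordering(strong_bank)
        assert len(report) == len(strong_bank)
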