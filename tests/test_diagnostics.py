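"""Scale diagnostics: alpha, Mokken scaling, Q3, S-X2, likelihood-ratio DIF."""

import numpy as np
import pandas as pd
import pytest

import gradedcat as gc
from gradedcat.bank import InvalidInputError
from gradedcat.diagnostics import lord_wingersky
from conftest import guttman_matrix


class TestCronbachAlpha:
    def test_perfectly_correlated_pair(self):
        col = np.random.default_rng(0).integers(0, 4, size=200)
        assert gc.cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_spearman_brown_oracle_at_half_correlation(self):
        # two items correlating 0.5 -> alpha = 2r/(1+r) = 2/3
        rng = np.random.default_rng(1)
        z = rng.normal(size=100_000)
        x1 = np.round(3 * (z + rng.normal(size=z.size)))
        x2 = np.round(3 * (z + rng.normal(size=z.size)))
        x = np.column_stack([x1, x2]).astype(int)
        assert gc.cronbach_alpha(x) == pytest.approx(2 * 0.5 / 1.5, abs=0.01)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, size=(50_000, 5))
        assert abs(gc.cronbach_alpha(x)) < 0.02

    def test_zero_total_variance_rejected(self):
        x = np.tile([1, 2], (10, 1))
        with pytest.raises(InvalidInputError):
            gc.cronbach_alpha(x)


class TestMokken:
    def test_perfect_guttman_data_scale_h_is_one(self):
        x = guttman_matrix(1000)
        res = gc.mokken_analysis(x, n_bootstrap=20)
        assert res.H_scale == pytest.approx(1.0, abs=1e-12)
        assert all(v == pytest.approx(1.0) for v in res.H_items.values())
        assert set(res.accuracy_labels.values()) == {"good"}

    def test_independent_items_scale_h_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, size=(50_000, 6))
        res = gc.mokken_analysis(x, n_bootstrap=0)
        assert abs(res.H_scale) < 0.03

    def test_strong_grm_scale_is_good_ordering(self, strong_bank):
        rng = np.random.default_rng(4)
        matrix = gc.simulate_responses(strong_bank, rng.normal(size=2000), seed=5)
        res = gc.mokken_analysis(matrix, n_bootstrap=50)
        assert res.H_scale > 0.5
        assert res.se_scale < 0.05

    def test_h_increases_with_discrimination(self):
        rng = np.random.default_rng(6)
        theta = rng.normal(size=3000)
        hs = []
        for a in (0.8, 1.6, 3.2):
            items = tuple(
                gc.ItemParameters(f"i{k}", a, (-0.5 + 0.1 * k, 0.4 + 0.1 * k, 1.3 + 0.1 * k))
                for k in range(5)
            )
            bank = gc.ItemBank(items=items, n_categories=4)
            matrix = gc.simulate_responses(bank, theta, seed=7)
            hs.append(gc.mokken_analysis(matrix, n_bootstrap=0).H_scale)
        assert hs[0] < hs[1] < hs[2]

    def test_all_coefficients_at_most_one(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        res = gc.mokken_analysis(matrix, bank.scales["stress"], n_bootstrap=0)
        pairs = res.H_pairs.to_numpy()
        assert np.nanmax(pairs) <= 1.0 + 1e-12
        assert res.H_scale <= 1.0
        assert max(res.H_items.values()) <= 1.0

    def test_accuracy_labels_follow_cut_points(self):
        from gradedcat.diagnostics import _accuracy_label

        assert [_accuracy_label(v) for v in (0.29, 0.3, 0.39, 0.4, 0.49, 0.5, 0.8)] == [
            "inaccurate", "low", "low", "moderate", "moderate", "good", "good",
        ]

    def test_zero_variance_item_named(self):
        x = np.column_stack([np.ones(300, dtype=int), np.random.default_rng(0).integers(0, 4, 300)])
        with pytest.raises(InvalidInputError, match="item1"):
            gc.mokken_analysis(x, n_bootstrap=0)


class TestAisp:
    def test_strong_scale_plus_noise_items_separated(self, strong_bank):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(10):
            theta = rng.normal(size=1000)
            matrix = gc.simulate_responses(strong_bank, theta, seed=100 + rep)
            df = matrix.data.copy()
            df["noise1"] = rng.integers(0, 4, size=1000)
            df["noise2"] = rng.integers(0, 4, size=1000)
            sel = gc.automated_item_selection(df)
            if (
                sorted(strong_bank.item_ids) in [sorted(s) for s in sel["scales"]]
                and set(sel["unscalable"]) >= {"noise1", "noise2"}
            ):
                hits += 1
        assert hits >= 9

    def test_independent_items_form_no_scale(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 4, size=(2000, 5))
        sel = gc.automated_item_selection(x)
        assert sel["scales"] == []
        assert len(sel["unscalable"]) == 5

    def test_zero_bound_pools_positively_correlated_items(self, strong_bank):
        rng = np.random.default_rng(10)
        matrix = gc.simulate_responses(strong_bank, rng.normal(size=1500), seed=11)
        sel = gc.automated_item_selection(matrix, lower_bound=0.0)
        assert sorted(sel["scales"][0]) == sorted(strong_bank.item_ids)
        assert sel["unscalable"] == []


class TestMonotonicity:
    def test_grm_generated_data_show_no_violations(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        results = []
        for scale, ids in bank.scales.items():
            results += gc.monotonicity_check(matrix, ids)
        clean = sum(1 for r in results if r["n_violations"] == 0)
        assert clean >= 0.95 * len(results)

    def test_reversed_item_detected(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        ids = bank.scales["depression"]
        df = matrix.data[ids].copy()
        df["dep1"] = 3 - df["dep1"]  # anti-monotone negative control
        results = gc.monotonicity_check(df)
        by_item = {r["item"]: r for r in results}
        assert by_item["dep1"]["n_violations"] > 0

    def test_one_entry_per_item(self, default_dataset):
        _c, bank, _t, matrix = default_dataset
        ids = bank.scales["anxiety"]
        assert len(gc.monotonicity_check(matrix, ids)) == len(ids)


class TestYenQ3:
    def test_matrix_symmetric_unit_diagonal(self, depression_calibration):
        _bank, matrix, result = depression_calibration
        q3 = gc.yen_q3(matrix, result.bank)
        mat = q3.residual_correlations.to_numpy()
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)

    def test_locally_independent_data_not_flagged(self, depression_calibration):
        _bank, matrix, result = depression_calibration
        q3 = gc.yen_q3(matrix, result.bank)
        assert q3.flagged_pairs == []
        off = q3.residual_correlations.to_numpy()[np.triu_indices(7, 1)]
        assert off.mean() < 0.0  # known negative bias under independence

    def test_duplicate_item_pair_flagged(self, depression_calibration):
        # score the duplicate as a candidate item against the clean calibration
        # (joint recalibration with an exact duplicate is degenerate: the
        # pair's discriminations diverge and mask the dependence)
        _bank, matrix, result = depression_calibration
        dup = gc.inject_dependence(matrix, "duplicate_item", {"item": "dep1", "noise": 0.15})
        dep1 = result.bank["dep1"]
        extended = gc.ItemBank(
            items=result.bank.items
            + (gc.ItemParameters("dep1_dup", dep1.a, dep1.b, scale=dep1.scale),),
            n_categories=4,
        )
        q3 = gc.yen_q3(dup, extended)
        flagged_pairs = [set(p[:2]) for p in q3.flagged_pairs]
        assert {"dep1", "dep1_dup"} in flagged_pairs
        assert q3.residual_correlations.loc["dep1", "dep1_dup"] > 0.20

    def test_zero_variance_column_reported_undefined(self, strong_bank):
        rng = np.random.default_rng(12)
        x = pd.DataFrame(
            rng.integers(0, 4, size=(300, 7)), columns=strong_bank.item_ids
        )
        x["s1"] = 1  # constant responses: residual variance ~ 0 given theta-hat
        q3 = gc.yen_q3(x, strong_bank)
        assert all("s1" in pair for pair in q3.undefined_pairs) or q3.undefined_pairs == []


class TestSX2:
    def test_lord_wingersky_rows_normalized(self, strong_bank):
        grid = gc.make_grid()
        probs = [
            gc.category_probabilities(it, grid.points) for it in strong_bank.items
        ]
        dist = lord_wingersky(probs)
        assert dist.shape == (61, 7 * 3 + 1)
        np.testing.assert_allclose(dist.sum(axis=1), 1.0, atol=1e-10)

    def test_model_consistent_data_mostly_fit(self, depression_calibration):
        _bank, matrix, result = depression_calibration
        table = gc.s_x2_item_fit(matrix, result.bank)
        assert len(table) == 7
        assert table["testable"].all()
        assert (table["p"] > 0.01).sum() >= 6  # at most one small-p item expected

    def test_distorted_item_rejected(self, default_dataset):
        _c, bank, thetas, matrix = default_dataset
        ids = bank.scales["depression"]
        df = matrix.data[ids].copy()
        # non-monotone response rule cannot be captured by any GRM
        df["dep1"] = (np.abs(thetas.values) < 0.8).astype(int) * 3
        cal = gc.calibrate_grm(df, se_method="none")
        table = gc.s_x2_item_fit(df, cal)
        p_bad = table.loc[table["item"] == "dep1", "p"].iloc[0]
        assert p_bad < 0.01

    def test_df_accounts_for_item_parameters(self, depression_calibration):
        _bank, matrix, result = depression_calibration
        table = gc.s_x2_item_fit(matrix, result.bank)
        assert (table["df"] >= 1).all()
        assert (table["rmsea"] >= 0).all()


class TestDif:
    @pytest.fixture(scope="class")
    def dif_data(self):
        cfg = gc.GenerationConfig(
            n_respondents=1000, n_scales=1, seed=31,
            injections=(("dif_shift", {"item": "dep3", "group": "B", "shift": 0.75}),),
        )
        return gc.generate_dataset(cfg)

    def test_shifted_item_flagged_others_not(self, dif_data):
        bank, _t, matrix = dif_data
        res = gc.dif_likelihood_ratio(matrix)
        assert "dep3" in res.flagged
        assert len(res.flagged) == 1

    def test_statistics_nonnegative_with_correct_df(self, dif_data):
        _bank, _t, matrix = dif_data
        res = gc.dif_likelihood_ratio(matrix)
        assert (res.table["lr"] >= 0).all()
        assert (res.table["df"] == 4).all()

    def test_relabeling_groups_preserves_statistics(self, dif_data):
        _bank, _t, matrix = dif_data
        res_ab = gc.dif_likelihood_ratio(matrix)
        swapped = np.where(matrix.group == "A", "Z", "A")  # Z sorts after A
        res_ba = gc.dif_likelihood_ratio(
            gc.ResponseMatrix(data=matrix.data, group=swapped)
        )
        np.testing.assert_allclose(
            res_ab.table["lr"].to_numpy(), res_ba.table["lr"].to_numpy(), atol=0.05
        )

    def test_missing_group_category_skips_item(self, dif_data):
        bank, _t, matrix = dif_data
        df = matrix.data.copy()
        mask = matrix.group == "B"
        col = df["dep5"].to_numpy().copy()
        col[mask & (col == 3)] = 2  # group B never reaches the top category
        df["dep5"] = col
        with pytest.warns(UserWarning, match="dep5"):
            res = gc.dif_likelihood_ratio(
                gc.ResponseMatrix(data=df, group=matrix.group)
            )
        assert "dep5" in res.skipped
        assert "dep5" not in res.table["item"].tolist()

    def test_requires_exactly_two_groups(self, dif_data):
        _bank, _t, matrix = dif_data
        bad = np.resize(np.array(["A", "B", "C"]), matrix.n_respondents)
        with pytest.raises(InvalidInputError):
            gc.dif_likelihood_ratio(gc.ResponseMatrix(data=matrix.data, group=bad))
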