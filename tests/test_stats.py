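"""Group statistics: hand oracles, library cross-checks, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sampenmap as sm
from sampenmap.errors import (
    ConstantInputError,
    OutOfRangeError,
    SubjectMismatchError,
    TooFewScansError,
    TooFewSubjectsError,
    UnbalancedDesignError,
)
from sampenmap.parcellation import RoiEntropyTable

import oracles


def _table_from_matrix(values, meta=None, classes=None):
    """A RoiEntropyTable wrapping a plain scans x ROIs matrix."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    names = [f"roi{i + 1}" for i in range(k)]
    if meta is None:
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i + 1}" for i in range(n)],
                "condition": ["rest"] * n,
                "scan_index": [1] * n,
            }
        )
    roi_info = pd.DataFrame(
        {
            "label": range(1, k + 1),
            "name": names,
            "class": classes or ["cortical"] * k,
        }
    )
    mean = pd.DataFrame(values, columns=names)
    ones = pd.DataFrame(np.ones_like(values), columns=names)
    return RoiEntropyTable(meta=meta, mean=mean, sd=ones * 0, n_valid=ones, roi_info=roi_info)


class TestPearson:
    def test_identity_and_affine_antisymmetry(self, rng):
        x = rng.normal(size=50)
        assert sm.pearson(x, x)[0] == pytest.approx(1.0)
        assert sm.pearson(x, -x + 5)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=(2, 200))
        r, p = sm.pearson(x, y)
        r0, p0 = oracles.textbook_pearson(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, rel=1e-10)

    def test_frozen_hand_values(self):
        r, p = sm.pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(0.821994936526786, abs=1e-10)
        assert p == pytest.approx(0.0877066470080655, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            sm.pearson([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestCorrelationMatrix:
    def test_identical_columns_all_ones(self):
        col = np.linspace(0, 1, 10)
        table = _table_from_matrix(np.column_stack([col] * 4))
        cm = sm.correlation_matrix(table)
        assert np.allclose(cm.values.to_numpy(), 1.0)

    def test_symmetry_unit_diagonal_psd(self, rng):
        table = _table_from_matrix(rng.normal(size=(40, 6)))
        cm = sm.correlation_matrix(table)
        v = cm.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert np.all(np.abs(v) <= 1 + 1e-12)
        assert np.linalg.eigvalsh(v).min() > -1e-8

    def test_independent_noise_has_small_offdiagonals(self, rng):
        table = _table_from_matrix(rng.normal(size=(200, 7)))
        v = sm.correlation_matrix(table).values.to_numpy()
        off = v[~np.eye(7, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.15

    def test_shared_factor_raises_offdiagonals_monotonically(self, rng):
        mean_rs = []
        for share in (0.0, 0.5, 0.9):
            f = rng.normal(size=(300, 1))
            data = math.sqrt(share) * f + math.sqrt(1 - share) * rng.normal(size=(300, 7))
            v = sm.correlation_matrix(_table_from_matrix(data)).values.to_numpy()
            mean_rs.append(v[~np.eye(7, dtype=bool)].mean())
        assert mean_rs[0] < mean_rs[1] < mean_rs[2]

    def test_listwise_missing_row_dropped(self, rng):
        data = rng.normal(size=(30, 3))
        data[4, 1] = np.nan
        cm = sm.correlation_matrix(_table_from_matrix(data))
        assert cm.n_scans == 29

    def test_too_few_scans_rejected(self, rng):
        with pytest.raises(TooFewScansError):
            sm.correlation_matrix(_table_from_matrix(rng.normal(size=(2, 3))))


class TestPairedTTest:
    def test_zero_mean_difference(self):
        rest = np.array([1.0, 2.0, 3.0, 4.0])
        task = rest + np.array([0.5, -0.5, 0.5, -0.5])
        res = sm.paired_ttest(rest, task)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_identical_nonzero_differences_degenerate(self):
        res = sm.paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.note == "zero-variance-diff"
        assert math.isnan(res.t_stat)
        assert res.mean_diff == pytest.approx(1.0)

    def test_frozen_hand_values(self):
        res = sm.paired_ttest([1, 2, 3, 4, 5], [0.5, 1.8, 2.2, 3.9, 4.1], 3)
        assert res.t_stat == pytest.approx(3.16227766016838, abs=1e-10)
        assert res.p_raw == pytest.approx(0.0341094231674096, abs=1e-10)
        assert res.p_adjusted == pytest.approx(3 * 0.0341094231674096, abs=1e-9)
        assert res.df == 4

    def test_known_shift_recovered(self, rng):
        delta, sigma, n = 0.3, 1.0, 200
        rest = rng.normal(size=n)
        task = rest - delta + rng.normal(scale=sigma, size=n)
        res = sm.paired_ttest(rest, task)
        # t should be near delta / (sigma / sqrt(n))
        assert res.t_stat == pytest.approx(delta / (sigma / math.sqrt(n)), rel=0.5)
        assert res.mean_diff > 0


class TestBonferroni:
    def test_arithmetic(self):
        assert sm.bonferroni([0.01]) == [0.01]
        assert sm.bonferroni([0.01, 0.2, 0.5, 0.9]) == [0.04, 0.8, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(OutOfRangeError):
            sm.bonferroni([0.5, 1.2])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_order_preserving_and_capped(self, ps):
        adj = sm.bonferroni(ps)
        order = np.argsort(ps, kind="stable")
        assert all(adj[i] <= adj[j] + 1e-15 for i, j in zip(order, order[1:]))
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p for a, p in zip(adj, ps))


class TestTwoFactorAnova:
    def test_frozen_hand_values_2x2(self):
        # 2x2, 3 obs/cell; SS and F cross-checked against a reference
        # least-squares fit outside this package
        y = [1, 2, 3, 2, 4, 6, 1, 1, 1, 3, 5, 7]
        a = ["a1"] * 6 + ["a2"] * 6
        b = (["b1"] * 3 + ["b2"] * 3) * 2
        table = sm.two_factor_anova(y, a, b).table.set_index("source")
        assert table.loc["factor_a", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["factor_b", "sum_sq"] == pytest.approx(27.0, abs=1e-10)
        assert table.loc["interaction", "sum_sq"] == pytest.approx(3.0, abs=1e-10)
        assert table.loc["error", "sum_sq"] == pytest.approx(18.0, abs=1e-10)
        assert table.loc["total", "sum_sq"] == pytest.approx(48.0, abs=1e-10)
        assert table.loc["factor_b", "F"] == pytest.approx(12.0, abs=1e-10)
        assert table.loc["factor_b", "p"] == pytest.approx(0.0085162633709, abs=1e-10)
        assert table.loc["interaction", "F"] == pytest.approx(4.0 / 3.0, abs=1e-10)
        assert table.loc["interaction", "p"] == pytest.approx(0.281536920111, abs=1e-10)
        assert list(table["df"]) == [1, 1, 1, 8, 11]

    def test_matches_statsmodels_on_random_balanced_design(self, rng):
        import statsmodels.api as smapi
        from statsmodels.formula.api import ols

        y = rng.normal(size=24)
        a = np.repeat(["u", "v"], 12)
        b = np.tile(np.repeat(["x", "y", "z"], 4), 2)
        mine = sm.two_factor_anova(y, a, b).table.set_index("source")
        ref = smapi.stats.anova_lm(
            ols("y ~ C(a)*C(b)", pd.DataFrame({"y": y, "a": a, "b": b})).fit(), typ=2
        )
        assert mine.loc["factor_a", "sum_sq"] == pytest.approx(ref.loc["C(a)", "sum_sq"], rel=1e-9)
        assert mine.loc["factor_b", "sum_sq"] == pytest.approx(ref.loc["C(b)", "sum_sq"], rel=1e-9)
        assert mine.loc["interaction", "sum_sq"] == pytest.approx(
            ref.loc["C(a):C(b)", "sum_sq"], rel=1e-9
        )
        assert mine.loc["factor_b", "p"] == pytest.approx(ref.loc["C(b)", "PR(>F)"], rel=1e-9)

    def test_partitioning_invariant(self, rng):
        y = rng.normal(size=40)
        a = np.repeat(["r", "t"], 20)
        b = np.tile(np.repeat(list("pqrst"), 4), 2)
        t = sm.two_factor_anova(y, a, b).table.set_index("source")
        parts = t.loc[["factor_a", "factor_b", "interaction", "error"], "sum_sq"].sum()
        assert parts == pytest.approx(t.loc["total", "sum_sq"], rel=1e-10)
        assert t.loc[["factor_a", "factor_b", "interaction", "error"], "df"].sum() == t.loc[
            "total", "df"
        ]
        assert (t["sum_sq"] >= -1e-12).all()

    def test_constant_response_reports_missing_f(self):
        y = np.ones(8)
        a = np.repeat(["u", "v"], 4)
        b = np.tile(["x", "x", "y", "y"], 2)
        t = sm.two_factor_anova(y, a, b).table.set_index("source")
        assert t["sum_sq"].abs().max() == pytest.approx(0.0, abs=1e-20)
        assert math.isnan(t.loc["factor_a", "F"])

    def test_unbalanced_rejected(self):
        with pytest.raises(UnbalancedDesignError):
            sm.two_factor_anova(
                [1.0, 2, 3, 4, 5], ["u", "u", "u", "v", "v"], ["x", "y", "x", "x", "y"]
            )

    def test_interaction_null_calibration(self, rng):
        # additive main effects only: interaction p should be ~ Uniform(0,1)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            a_eff = {"u": 0.0, "v": 0.4}
            b_eff = {"x": -0.2, "y": 0.0, "z": 0.3}
            a = np.repeat(["u", "v"], 15)
            b = np.tile(np.repeat(["x", "y", "z"], 5), 2)
            y = np.array([a_eff[ai] + b_eff[bi] for ai, bi in zip(a, b)]) + rng.normal(size=30)
            p = sm.two_factor_anova(y, a, b).table.set_index("source").loc["interaction", "p"]
            rejections += p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.08


class TestIcc:
    def test_identical_scans_give_one(self):
        assert sm.icc_3_1([1.0, 2, 3, 4], [1.0, 2, 3, 4]).icc == pytest.approx(1.0)

    def test_consistency_form_ignores_constant_offset(self):
        res = sm.icc_3_1([1.0, 2, 3, 4], [3.5, 4.5, 5.5, 6.5])
        assert res.icc == pytest.approx(1.0)

    def test_frozen_hand_values(self):
        # cross-checked against an independent ICC(3,1) implementation
        res = sm.icc_3_1([1.0, 2, 3, 4], [2.0, 2, 4, 5])
        assert res.icc == pytest.approx(44.0 / 47.0, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        s1 = rng.normal(size=12)
        s2 = 0.7 * s1 + rng.normal(scale=0.5, size=12)
        res = sm.icc_3_1(s1, s2)
        d = pd.DataFrame(
            {
                "subj": list(range(12)) * 2,
                "rater": ["r1"] * 12 + ["r2"] * 12,
                "y": np.concatenate([s1, s2]),
            }
        )
        ref = pg.intraclass_corr(d, targets="subj", raters="rater", ratings="y")
        ref31 = float(ref.loc[ref["Type"].isin(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0])
        assert res.icc == pytest.approx(ref31, abs=1e-10)

    def test_recovers_planted_reliability(self, rng):
        for rho in (0.2, 0.5, 0.8):
            estimates = []
            for _ in range(60):
                s = rng.normal(scale=math.sqrt(rho), size=200)
                e1 = rng.normal(scale=math.sqrt(1 - rho), size=200)
                e2 = rng.normal(scale=math.sqrt(1 - rho), size=200)
                estimates.append(sm.icc_3_1(s + e1, s + e2).icc)
            assert np.mean(estimates) == pytest.approx(rho, abs=0.05)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(TooFewSubjectsError):
            sm.icc_3_1([1.0, 2], [1.0, 2])


class TestScanConsistency:
    def _pair_tables(self, v1, v2):
        n = v1.shape[0]
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i + 1}" for i in range(n)],
                "condition": ["rest"] * n,
                "scan_index": [1] * n,
            }
        )
        return _table_from_matrix(v1, meta=meta), _table_from_matrix(v2, meta=meta.copy())

    def test_identical_tables_fully_consistent(self, rng):
        v = rng.normal(size=(10, 4))
        t1, t2 = self._pair_tables(v, v.copy())
        per_roi, group_r = sm.scan_consistency(t1, t2)
        assert np.allclose(per_roi["icc"], 1.0)
        assert np.allclose(per_roi["r"], 1.0)
        assert group_r == pytest.approx(1.0)

    def test_independent_scans_have_low_icc(self, rng):
        iccs = []
        for _ in range(50):
            t1, t2 = self._pair_tables(rng.normal(size=(40, 3)), rng.normal(size=(40, 3)))
            per_roi, _ = sm.scan_consistency(t1, t2)
            iccs.extend(per_roi["icc"])
        assert abs(float(np.mean(iccs))) < 0.07

    def test_planted_subject_effect_recovered(self, rng):
        rho = 0.5
        iccs = []
        for _ in range(40):
            s = rng.normal(scale=math.sqrt(rho), size=(200, 2))
            v1 = s + rng.normal(scale=math.sqrt(1 - rho), size=(200, 2))
            v2 = s + rng.normal(scale=math.sqrt(1 - rho), size=(200, 2))
            per_roi, _ = sm.scan_consistency(*self._pair_tables(v1, v2))
            iccs.extend(per_roi["icc"])
        assert np.mean(iccs) == pytest.approx(rho, abs=0.05)

    def test_subject_mismatch_rejected(self, rng):
        t1, t2 = self._pair_tables(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        t2.meta.loc[0, "subject_id"] = "someone_else"
        with pytest.raises(SubjectMismatchError):
            sm.scan_consistency(t1, t2)
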