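"""Percent error, Spearman, correlation categories, ICC (with two
independent oracles), robust selection, and leave-p-out enumeration."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radstab.core import ConfigurationError, FeatureTable
from radstab.stats import (
    classify_correlation,
    correlate_error_with_dice,
    icc_per_feature,
    icc_two_way,
    leave_p_out,
    percent_error,
    select_robust,
    spearman,
)

# Shrout & Fleiss's classic 6-target × 4-judge reliability table
SF_TABLE = np.array(
    [[9, 2, 5, 8], [6, 1, 3, 2], [8, 4, 6, 8], [7, 1, 2, 6], [10, 5, 6, 9], [6, 2, 4, 7]],
    dtype=float,
)


class TestPercentError:
    @pytest.mark.parametrize(
        "f,f_gt,expected",
        [(110.0, 100.0, 10.0), (5.0, 5.0, 0.0), (-0.5, -0.4, -25.0)],
    )
    def test_examples(self, f, f_gt, expected):
        assert percent_error(f, f_gt) == pytest.approx(expected)

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            percent_error(1.0, 0.0)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 3.0, 8.0, 20.0])[0] == pytest.approx(1.0)
        assert spearman(x, [4.0, 3.0, 1.0, 0.5])[0] == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([3.0, 3.0, 5.0, 7.0, 7.0])

        def avg_ranks(v):  # hand-rolled average ranking
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, rel=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            (-0.6277, "relatively strong"),
            (0.400, "moderate"),
            (0.0, "weak"),
            (0.399999, "weak"),
            (0.599999, "moderate"),
            (0.600, "relatively strong"),
            (0.800, "strong"),
            (-1.0, "strong"),
        ],
    )
    def test_boundaries(self, rho, expected):
        assert classify_correlation(rho) == expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_total_step_function(self, rho):
        cat = classify_correlation(rho)
        bounds = {"weak": (0, 0.4), "moderate": (0.4, 0.6),
                  "relatively strong": (0.6, 0.8), "strong": (0.8, 1.0 + 1e-9)}
        lo, hi = bounds[cat]
        assert lo <= abs(rho) < hi or (cat == "strong" and abs(rho) == 1.0)


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 4))
        r = icc_two_way(x)
        assert r.icc == r.lb == r.ub == 1.0

    def test_zero_variance_degenerate(self):
        r = icc_two_way(np.ones((5, 5)))
        assert r.degenerate and np.isnan(r.icc)

    def test_against_explicit_anova_oracle(self):
        """Hand-computed sums of squares on the classic 6×4 table."""
        x = SF_TABLE
        n, k = x.shape
        grand = x.mean()
        ss_rows = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
        ss_cols = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
        msr = ss_rows / (n - 1)
        msc = ss_cols / (k - 1)
        mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        r = icc_two_way(x)
        assert r.icc == pytest.approx(expected, rel=1e-12)
        assert r.lb < r.icc < r.ub

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, k = SF_TABLE.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "y": SF_TABLE.ravel(),
            }
        )
        out = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="y")
        row = out[out["Type"] == "ICC(A,1)"].iloc[0]
        r = icc_two_way(SF_TABLE)
        assert r.icc == pytest.approx(float(row["ICC"]), rel=1e-9)
        lo, hi = row["CI95"]
        assert r.lb == pytest.approx(lo, abs=5e-3)
        assert r.ub == pytest.approx(hi, abs=5e-3)
        row_k = out[out["Type"] == "ICC(A,k)"].iloc[0]
        rk = icc_two_way(SF_TABLE, form="average")
        assert rk.icc == pytest.approx(float(row_k["ICC"]), rel=1e-9)

    @pytest.mark.parametrize("a,b", [(10.0, 1.0), (0.0, 3.5), (-2.0, 0.25)])
    def test_affine_invariance(self, a, b):
        """ICC is invariant to y → a + b·y with b > 0."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 3, (8, 1)) + rng.normal(0, 1, (8, 5))
        r1 = icc_two_way(x)
        r2 = icc_two_way(a + b * x)
        assert r1.icc == pytest.approx(r2.icc, rel=1e-10)
        assert r1.lb == pytest.approx(r2.lb, rel=1e-9)

    def test_no_lesion_effect_gives_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [icc_two_way(rng.normal(0, 1, (26, 10))).icc for _ in range(50)]
        assert abs(np.mean(vals)) < 0.05

    def test_rejects_incomplete_or_tiny(self):
        with pytest.raises(ValueError):
            icc_two_way(np.ones((1, 4)))
        bad = np.ones((4, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_two_way(bad)


def _table_from_matrix(mat, feature="f", G=32):
    """Build a FeatureTable whose rater matrix for (feature, G) is ``mat``."""
    n, k = mat.shape
    recs = []
    for i in range(n):
        recs.append(
            {"lesion_id": f"l{i:02d}", "source": "ground_truth",
             "gray_levels": G, "feature": feature, "value": 0.0}
        )
        for j in range(k):
            recs.append(
                {"lesion_id": f"l{i:02d}", "source": f"r{j:02d}",
                 "gray_levels": G, "feature": feature, "value": mat[i, j]}
            )
    return FeatureTable.from_records(recs)


class TestPerFeatureICC:
    def test_matches_direct_call(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 1, (6, 4)) + rng.normal(0, 2, (6, 1))
        table = _table_from_matrix(mat)
        [res] = icc_per_feature(table)
        direct = icc_two_way(mat)
        assert res.icc == pytest.approx(direct.icc, rel=1e-12)
        assert (res.n_targets, res.k_raters) == (6, 4)

    def test_missing_cell_named(self):
        mat = np.ones((4, 3)) + np.arange(4)[:, None]
        table = _table_from_matrix(mat)
        df = table.df[~((table.df.lesion_id == "l01") & (table.df.source == "r01"))]
        broken = FeatureTable(df.reset_index(drop=True))
        with pytest.raises(ValueError, match="l01"):
            icc_per_feature(broken)


class TestSelectRobust:
    def test_threshold_inclusive(self):
        from radstab.stats import ICCResult

        mk = lambda lb: ICCResult("f", 32, 0.99, lb, 1.0, 26, 10)
        assert select_robust([mk(0.950)]) == [("f", 32)]
        assert select_robust([mk(0.949)]) == []


class TestLeavePOut:
    def test_exhaustive_enumeration_k5(self):
        """p ∈ {1, 2} for 5 raters equals independent subset enumeration."""
        rng = np.random.default_rng(5)
        mat = rng.normal(0, 1, (8, 5)) + rng.normal(0, 2, (8, 1))
        table = _table_from_matrix(mat)
        [curve] = leave_p_out(table, [("f", 32)], p_max=2)
        for p in (1, 2):
            subs = list(combinations(range(5), 5 - p))
            lbs = [icc_two_way(mat[:, list(c)]).lb for c in subs]
            assert curve.n_subsets[p] == len(subs)
            assert curve.mean_lb[p] == pytest.approx(np.mean(lbs), rel=1e-12)
        assert curve.n_subsets[1] == 5 and curve.n_subsets[2] == 10

    def test_subset_count_k10_p3(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(0, 1, (5, 10)) + rng.normal(0, 3, (5, 1))
        table = _table_from_matrix(mat)
        [curve] = leave_p_out(table, [("f", 32)], p_max=3)
        assert curve.n_subsets[3] == 120  # C(10, 7)

    def test_p_max_too_large_rejected(self):
        mat = np.random.default_rng(0).normal(size=(4, 4))
        table = _table_from_matrix(mat)
        with pytest.raises(ConfigurationError):
            leave_p_out(table, [("f", 32)], p_max=3)


class TestCorrelateErrorWithDice:
    def _scores(self, dice_map):
        return pd.DataFrame(
            [
                {"lesion_id": l, "rater_id": r, "dice": d, "smasd": 0.1,
                 "volume_error_cm3": 0.0}
                for (l, r), d in dice_map.items()
            ]
        )

    def test_monotone_construction_gives_rho_minus_one(self):
        """Feature error falls strictly with Dice → ρ = −1."""
        lesions = [f"l{i}" for i in range(4)]
        raters = [f"r{j}" for j in range(3)]
        rng = np.random.default_rng(2)
        dice_map, recs = {}, []
        for l in lesions:
            recs.append({"lesion_id": l, "source": "ground_truth",
                         "gray_levels": 32, "feature": "f", "value": 100.0})
        for i, (l, r) in enumerate(product(lesions, raters)):
            d = 0.99 - 0.05 * i
            dice_map[(l, r)] = d
            recs.append({"lesion_id": l, "source": r, "gray_levels": 32,
                         "feature": "f", "value": 100.0 * (2.0 - d)})
        table = FeatureTable.from_records(recs)
        [res] = correlate_error_with_dice(table, self._scores(dice_map))
        assert res.rho == pytest.approx(-1.0)
        assert res.category == "strong"
        assert res.n_pairs == 12

    def test_constant_error_skipped_with_warning(self):
        lesions, raters = ["l0", "l1", "l2"], ["r0", "r1"]
        recs = [
            {"lesion_id": l, "source": "ground_truth", "gray_levels": 32,
             "feature": "f", "value": 10.0}
            for l in lesions
        ] + [
            {"lesion_id": l, "source": r, "gray_levels": 32,
             "feature": "f", "value": 11.0}
            for l in lesions for r in raters
        ]
        dice_map = {(l, r): 0.8 + 0.01 * i
                    for i, (l, r) in enumerate(product(lesions, raters))}
        table = FeatureTable.from_records(recs)
        with pytest.warns(UserWarning, match="rho undefined"):
            out = correlate_error_with_dice(table, self._scores(dice_map))
        assert out == []

    def test_zero_ground_truth_pairs_excluded(self):
        lesions, raters = ["l0", "l1", "l2", "l3"], ["r0", "r1"]
        recs = []
        for i, l in enumerate(lesions):
            recs.append({"lesion_id": l, "source": "ground_truth",
                         "gray_levels": 32, "feature": "f",
                         "value": 0.0 if l == "l0" else 50.0 + i})
        rng = np.random.default_rng(0)
        for l in lesions:
            for r in raters:
                recs.append({"lesion_id": l, "source": r, "gray_levels": 32,
                             "feature": "f", "value": rng.uniform(40, 60)})
        dice_map = {(l, r): rng.uniform(0.7, 1.0) for l in lesions for r in raters}
        table = FeatureTable.from_records(recs)
        with pytest.warns(UserWarning, match="excluded"):
            [res] = correlate_error_with_dice(table, self._scores(dice_map))
        assert res.n_excluded == 2
        assert res.n_pairs == 6
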