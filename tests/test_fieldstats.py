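import math

import numpy as np
import pandas as pd
import pytest

from roboyield import fieldstats as fs
from roboyield.fieldstats import ConfusionCounts, FieldLayout


def grid_layout(n_ranges, n_passes, values, entries=None):
    rr, pp = np.meshgrid(np.arange(1, n_ranges + 1),
                         np.arange(1, n_passes + 1), indexing="ij")
    df = pd.DataFrame({"range": rr.ravel(), "pass": pp.ravel(),
                       "value": np.asarray(values, float).ravel()})
    df["entry"] = entries if entries is not None else 0
    return FieldLayout(df)


class TestGridMask:
    def test_mask_has_twenty_cells(self):
        assert len(fs.GRID_MASK) == 20

    def test_mask_symmetric_under_quarter_turns(self):
        cells = set(fs.GRID_MASK)
        rotated = {(-p, r) for r, p in cells}
        assert rotated == cells

    def test_mask_excludes_center_and_corners(self):
        assert (0, 0) not in fs.GRID_MASK
        for corner in ((2, 2), (2, -2), (-2, 2), (-2, -2)):
            assert corner not in fs.GRID_MASK


class TestMovingMean:
    def test_constant_field_gives_constant_means(self):
        layout = grid_layout(6, 6, np.full(36, 3.5))
        mm = fs.moving_mean(layout)
        assert np.allclose(mm["moving_mean"], 3.5)

    def test_interior_plot_uses_all_twenty_neighbors(self):
        layout = grid_layout(6, 6, np.arange(36.0))
        mm = fs.moving_mean(layout)
        center = mm[(mm["range"] == 3) & (mm["pass"] == 3)]
        assert center["n_neighbors"].iloc[0] == 20

    def test_corner_plot_matches_hand_enumeration(self):
        values = np.arange(25.0).reshape(5, 5)  # value = 5*(r-1) + (p-1)
        layout = grid_layout(5, 5, values)
        mm = fs.moving_mean(layout)
        corner = mm[(mm["range"] == 1) & (mm["pass"] == 1)]
        # in-bounds masked neighbours of (1,1): (1,2),(1,3),(2,1),(2,2),
        # (2,3),(3,1),(3,2) -> 7 cells
        expected_cells = [(1, 2), (1, 3), (2, 1), (2, 2), (2, 3), (3, 1), (3, 2)]
        expected = np.mean([values[r - 1, p - 1] for r, p in expected_cells])
        assert corner["n_neighbors"].iloc[0] == 7
        assert corner["moving_mean"].iloc[0] == pytest.approx(expected)

    def test_agrees_with_brute_force_on_random_field(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(3, 1, 64)
        layout = grid_layout(8, 8, vals)
        mm = fs.moving_mean(layout)
        lookup = {(r, p): v for r, p, v in
                  zip(layout.df["range"], layout.df["pass"], layout.df["value"])}
        for _, row in mm.iterrows():
            acc = [lookup[(row["range"] + dr, row["pass"] + dp)]
                   for dr in range(-2, 3) for dp in range(-2, 3)
                   if not (dr == 0 and dp == 0)
                   and not (abs(dr) == 2 and abs(dp) == 2)
                   and (row["range"] + dr, row["pass"] + dp) in lookup]
            assert row["moving_mean"] == pytest.approx(np.mean(acc))


class TestAdjustment:
    def test_phenotype_equal_to_moving_mean_gives_slope_one(self):
        # on a linear-gradient field the symmetric mask makes every interior
        # plot's moving mean equal its own value, so regressing the phenotype
        # on the moving means over those plots is the identity: slope 1
        rr, pp = np.meshgrid(np.arange(1, 11), np.arange(1, 11), indexing="ij")
        layout = grid_layout(10, 10, 1.0 + 0.4 * rr + 0.25 * pp)
        merged = layout.df.merge(fs.moving_mean(layout), on=["range", "pass"])
        interior = merged[merged["n_neighbors"] == 20]
        assert np.allclose(interior["moving_mean"], interior["value"])
        slope = np.polyfit(interior["moving_mean"], interior["value"], 1)[0]
        assert slope == pytest.approx(1.0)

    def test_pure_noise_slope_near_zero(self):
        rng = np.random.default_rng(2)
        n = 20
        layout = grid_layout(n, n, rng.normal(0, 1, n * n))
        model = fs.fit_adjustment(layout)
        # |b| < 3 SE of the slope estimate
        mm = fs.moving_mean(layout)["moving_mean"].to_numpy()
        y = layout.df["value"].to_numpy()
        resid = y - model.b * (mm - mm.mean()) - y.mean()
        se = np.sqrt(resid.var() / (mm.var() * len(y)))
        assert abs(model.b) < 3 * se

    def test_trend_only_field_variance_collapses(self):
        rr, pp = np.meshgrid(np.arange(1, 13), np.arange(1, 13), indexing="ij")
        trend = 0.3 * rr + 0.2 * pp
        layout = grid_layout(12, 12, trend)
        model = fs.fit_adjustment(layout)
        adjusted = fs.adjust(layout, model)
        assert adjusted.df["value_adj"].var() <= 0.2 * layout.df["value"].var()

    def test_zero_slope_is_identity(self):
        layout = grid_layout(5, 5, np.arange(25.0))
        model = fs.fit_adjustment(layout)
        model.b = 0.0
        adjusted = fs.adjust(layout, model)
        assert np.allclose(adjusted.df["value_adj"], layout.df["value"])

    def test_six_by_six_gradient_matches_hand_computation(self):
        """Adjusted values on a 6x6 linear-gradient field equal a cell-by-cell
        independent recomputation of p_obs - b*(x_i - x_bar)."""
        rr, pp = np.meshgrid(np.arange(1, 7), np.arange(1, 7), indexing="ij")
        obs = 2.0 + 0.5 * rr.astype(float)
        layout = grid_layout(6, 6, obs)
        model = fs.fit_adjustment(layout)
        adjusted = fs.adjust(layout, model)

        lookup = {(r, p): v for r, p, v in
                  zip(rr.ravel(), pp.ravel(), obs.ravel())}
        xi = {}
        for (r, p), v in lookup.items():
            neigh = [lookup[(r + dr, p + dp)] for dr, dp in fs.GRID_MASK
                     if (r + dr, p + dp) in lookup]
            xi[(r, p)] = np.mean(neigh)
        xs = np.array([xi[k] for k in lookup])
        ys = np.array(list(lookup.values()))
        b = np.polyfit(xs, ys, 1)[0]
        xbar = xs.mean()
        for _, row in adjusted.df.iterrows():
            key = (row["range"], row["pass"])
            expected = lookup[key] - b * (xi[key] - xbar)
            assert row["value_adj"] == pytest.approx(expected, abs=1e-9)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(3)
        layout = grid_layout(10, 10, rng.normal(3, 1, 100))
        model = fs.fit_adjustment(layout)
        adjusted = fs.adjust(layout, model)
        assert adjusted.df["value_adj"].mean() == pytest.approx(
            layout.df["value"].mean()
        )


class TestNormalizeYield:
    def test_standard_moisture_mass_unchanged(self):
        # at 13% the moisture factor is exactly 1: 1 kg on 10 m2 = 1 MT/ha
        assert fs.normalize_yield(1.0, 13.0, 10.0) == pytest.approx(1.0)

    def test_hand_computed_conversion(self):
        # 2.5 kg at 20% moisture: 2.5 * 80/87 kg at 13%; 3.24 m2 plot
        expected = (2.5 * 80 / 87 / 1000) / (3.24 / 10_000)
        assert fs.normalize_yield(2.5, 20.0, 3.24) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(fs.FieldStatsError):
            fs.normalize_yield(1.0, 100.0, 10.0)
        with pytest.raises(fs.FieldStatsError):
            fs.normalize_yield(1.0, 13.0, 0.0)


class TestConfusion:
    def test_identical_vectors_no_errors(self):
        v = np.arange(50.0)
        c = fs.confusion_at_threshold(v, v, 0.2)
        assert c.FP == 0 and c.FN == 0
        assert c.TP == 10 and c.TN == 40

    def test_anticorrelated_estimate_has_no_true_positives(self):
        v = np.arange(50.0)
        c = fs.confusion_at_threshold(v, -v, 0.5)
        assert c.TP == 0

    def test_counts_match_exhaustive_set_oracle(self):
        rng = np.random.default_rng(4)
        truth = rng.normal(3, 1, 650)
        estimate = 0.5 * truth + rng.normal(0, 1, 650)
        for q in (0.1, 0.2, 0.3):
            c = fs.confusion_at_threshold(truth, estimate, q)
            k = math.ceil(q * 650)
            top_t = set(np.argsort(-truth, kind="stable")[:k])
            top_e = set(np.argsort(-estimate, kind="stable")[:k])
            assert c.TP == len(top_t & top_e)
            assert c.FP == len(top_e - top_t)
            assert c.FN == len(top_t - top_e)
            assert c.n == 650
            assert c.FP == c.FN  # equal-size top sets force this

    def test_nan_pairs_excluded_with_warning(self):
        truth = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        est = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="NaN"):
            c = fs.confusion_at_threshold(truth, est, 0.5)
        assert c.n == 4

    def test_sensitivity_nondecreasing_in_q(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(0, 1, 300)
        est = 0.6 * truth + rng.normal(0, 1, 300)
        sens = [
            fs.selection_metrics(fs.confusion_at_threshold(truth, est, q))["sensitivity"]
            for q in (0.1, 0.2, 0.3)
        ]
        assert sens[0] <= sens[1] <= sens[2]


class TestSelectionMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(TP=20, TN=540, FP=45, FN=45),
             {"accuracy": 0.86, "sensitivity": 0.31, "specificity": 0.92}),
            (ConfusionCounts(TP=11, TN=531, FP=54, FN=54),
             {"accuracy": 0.83, "sensitivity": 0.17, "specificity": 0.91}),
        ],
    )
    def test_published_confusion_rows_reproduce(self, counts, expected):
        got = fs.selection_metrics(counts)
        for key, val in expected.items():
            assert round(got[key], 2) == val

    def test_perfect_classifier(self):
        got = fs.selection_metrics(ConfusionCounts(TP=10, TN=90, FP=0, FN=0))
        assert got == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            got = fs.selection_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(got["sensitivity"])
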