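"""Binning, cessation, outlier exclusion, group statistics and curve fits."""

import numpy as np
import pytest

from fishact import (
    ConditionGroup,
    bin_trace,
    compare_groups,
    detect_cessation,
    exclude_highest_variance,
    fit_linear,
    fit_sigmoid,
    heatmap_matrix,
    significance_stars,
)
from fishact.analysis import sigmoid

from conftest import make_trace


class TestBinTrace:
    def test_constant_trace_constant_bins(self):
        tr = make_trace([7.0] * 100, dt=1.0, t0=1.0)
        b = bin_trace(tr, 25.0)
        assert np.all(b.bin_means[~np.isnan(b.bin_means)] == 7.0)

    def test_ramp_bin_means_are_range_means(self):
        # samples at t = 1..600 s with value = t, 300 s bins:
        # [0,300) holds 1..299 (mean 150), [300,600) holds 300..599
        # (mean 449.5), [600,900) holds just 600
        tr = make_trace(np.arange(1, 601, dtype=float), dt=1.0, t0=1.0)
        b = bin_trace(tr, 300.0)
        assert b.bin_means[0] == pytest.approx(np.mean(np.arange(1, 300)))
        assert b.bin_means[1] == pytest.approx(np.mean(np.arange(300, 600)))
        assert b.bin_means[2] == pytest.approx(600.0)

    def test_empty_bins_are_nan_not_zero(self):
        tr = make_trace([5.0, 5.0], dt=1000.0, t0=1.0)
        b = bin_trace(tr, 300.0)
        assert b.bin_means[0] == 5.0
        assert np.isnan(b.bin_means[1])
        assert b.bin_means[3] == 5.0

    def test_bin_count_bounded_by_duration(self):
        tr = make_trace(np.ones(500), dt=1.0, t0=1.0)
        b = bin_trace(tr, 60.0)
        nonempty = np.count_nonzero(~np.isnan(b.bin_means))
        assert nonempty <= np.ceil(500 / 60.0) + 1

    def test_mean_preserving_on_full_equal_bins(self, rng):
        vals = rng.uniform(0, 100, size=600)
        tr = make_trace(vals, dt=1.0, t0=0.0)
        b = bin_trace(tr, 100.0)  # 6 bins of 100 samples each
        assert np.nanmean(b.bin_means) == pytest.approx(vals.mean())

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            bin_trace(make_trace([1.0]), 0.0)


class TestHeatmap:
    def make_groups(self):
        g1 = ConditionGroup("ctrl", [
            make_trace(np.full(60, 4.0), animal_id="a1", condition="ctrl"),
            make_trace(np.full(60, 4.0), animal_id="a2", condition="ctrl"),
        ])
        g2 = ConditionGroup("drug", [
            make_trace(np.linspace(10, 1, 60), animal_id="b1", condition="drug"),
        ])
        return [g1, g2]

    def test_shape_one_row_per_animal(self):
        m = heatmap_matrix(self.make_groups(), bin_width=10.0)
        assert m.shape == (3, 7)
        assert list(m.index) == [("ctrl", "a1"), ("ctrl", "a2"), ("drug", "b1")]

    def test_identical_traces_identical_rows(self):
        m = heatmap_matrix(self.make_groups(), bin_width=10.0)
        np.testing.assert_array_equal(m.iloc[0].to_numpy(), m.iloc[1].to_numpy())

    def test_cells_match_bin_trace(self):
        groups = self.make_groups()
        m = heatmap_matrix(groups, bin_width=10.0)
        b = bin_trace(groups[1].traces[0], 10.0)
        row = m.loc[("drug", "b1")].to_numpy()[: len(b.bin_means)]
        np.testing.assert_allclose(row, b.bin_means)

    def test_normalized_rows_peak_at_one(self):
        m = heatmap_matrix(self.make_groups(), bin_width=10.0, normalize=True)
        assert np.nanmax(m.to_numpy(), axis=1) == pytest.approx([1, 1, 1])

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            heatmap_matrix([], 10.0)


class TestDetectCessation:
    def test_all_zero_trace_ceases_at_start(self):
        tr = make_trace(np.zeros(100), dt=1.0, t0=1.0)
        assert detect_cessation(tr, epsilon=0.0, hold=50.0) == 1.0

    def test_always_active_returns_none(self):
        tr = make_trace(np.full(100, 3.0), dt=1.0, t0=1.0)
        assert detect_cessation(tr, epsilon=0.0, hold=10.0) is None

    def test_onset_of_terminal_quiet_period(self):
        vals = np.concatenate([np.full(50, 5.0), np.zeros(50)])
        tr = make_trace(vals, dt=1.0, t0=1.0)
        assert detect_cessation(tr, epsilon=0.0, hold=20.0) == 51.0

    def test_brief_dip_is_not_death(self):
        vals = np.concatenate([np.full(40, 5.0), np.zeros(10), np.full(50, 5.0)])
        tr = make_trace(vals, dt=1.0, t0=1.0)
        assert detect_cessation(tr, epsilon=0.0, hold=5.0) is None

    def test_short_terminal_quiet_below_hold_is_none(self):
        vals = np.concatenate([np.full(95, 5.0), np.zeros(5)])
        tr = make_trace(vals, dt=1.0, t0=1.0)
        assert detect_cessation(tr, epsilon=0.0, hold=20.0) is None

    def test_monotone_in_epsilon(self, rng):
        vals = np.concatenate([rng.uniform(2, 8, 60), rng.uniform(0, 0.5, 40)])
        tr = make_trace(vals, dt=1.0, t0=1.0)
        t_low = detect_cessation(tr, epsilon=0.5, hold=10.0)
        t_high = detect_cessation(tr, epsilon=1.0, hold=10.0)
        assert t_low is not None and t_high is not None
        assert t_high <= t_low


class TestExcludeHighestVariance:
    def test_planted_oscillator_removed(self, rng):
        quiet = [make_trace(np.full(50, 5.0) + rng.normal(0, 0.1, 50),
                            animal_id=f"q{i}") for i in range(4)]
        wobble = make_trace(5.0 + 20 * np.sin(np.arange(50)), animal_id="wob")
        group = ConditionGroup("c", quiet[:2] + [wobble] + quiet[2:])
        out = exclude_highest_variance(group)
        assert len(out.traces) == 4
        assert all(t.animal_id != "wob" for t in out.traces)

    def test_matches_brute_force_variance_scan(self, rng):
        traces = [make_trace(rng.uniform(0, 10, 30), animal_id=str(i))
                  for i in range(6)]
        group = ConditionGroup("c", traces)
        out = exclude_highest_variance(group)
        variances = [np.var(t.activities, ddof=1) for t in traces]
        expected_drop = traces[int(np.argmax(variances))].animal_id
        assert {t.animal_id for t in traces} - {t.animal_id for t in out.traces} \
            == {expected_drop}

    def test_tie_breaks_to_first(self):
        t1 = make_trace([0.0, 10.0], animal_id="first")
        t2 = make_trace([0.0, 10.0], animal_id="second")
        out = exclude_highest_variance(ConditionGroup("c", [t1, t2]))
        assert out.traces[0].animal_id == "second"

    def test_single_trace_rejected(self):
        with pytest.raises(ValueError):
            exclude_highest_variance(ConditionGroup("c", [make_trace([1.0])]))


class TestCompareGroups:
    @staticmethod
    def group_from_means(cond, means):
        return ConditionGroup(cond, [make_trace([m] * 10, animal_id=f"{cond}{i}",
                                                condition=cond)
                                     for i, m in enumerate(means)])

    def test_identical_groups_no_signal(self):
        g1 = self.group_from_means("a", [5.0, 5.0, 5.0])
        g2 = self.group_from_means("b", [5.0, 5.0, 5.0])
        comp = compare_groups([g1, g2])
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert all(p == pytest.approx(1.0, abs=1e-9) for *_, p in comp.tukey_pairs)

    def test_separated_groups_highly_significant(self, rng):
        g1 = self.group_from_means("lo", list(1 + rng.normal(0, 0.01, 4)))
        g2 = self.group_from_means("hi", list(10 + rng.normal(0, 0.01, 4)))
        comp = compare_groups([g1, g2])
        assert comp.tukey_pairs[0][2] < 0.001
        assert significance_stars(comp.tukey_pairs[0][2]) == "***"

    def test_f_statistic_matches_sums_of_squares_oracle(self, rng):
        data = {c: list(rng.uniform(0, 10, 5)) for c in ("a", "b", "c")}
        groups = [self.group_from_means(c, v) for c, v in data.items()]
        comp = compare_groups(groups)
        # textbook one-way ANOVA from sums of squares
        all_vals = np.concatenate(list(data.values()))
        grand = all_vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in data.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum()
                        for v in data.values())
        k, n = 3, len(all_vals)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert comp.f_statistic == pytest.approx(f_oracle, abs=1e-6)

    def test_tukey_covers_all_pairs(self, rng):
        groups = [self.group_from_means(c, list(rng.uniform(0, 10, 4)))
                  for c in ("a", "b", "c", "d")]
        comp = compare_groups(groups)
        assert len(comp.tukey_pairs) == 6
        assert all(0 <= p <= 1 for *_, p in comp.tukey_pairs)

    def test_degenerate_group_rejected(self):
        g1 = self.group_from_means("a", [1.0])
        g2 = self.group_from_means("b", [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_groups([g1, g2])


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_convention(self):
        fit = fit_linear([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 50, 40)
        y = 3 * x - 7 + rng.normal(0, 5, 40)
        fit = fit_linear(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-9)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-9)
        resid = y - X @ beta
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFitSigmoid:
    def test_noiseless_parameter_recovery(self):
        x = np.arange(0, 101, dtype=float)
        y = sigmoid(x, 100.0, 50.0, 10.0)
        fit = fit_sigmoid(x, y)
        assert fit.converged and not fit.degenerate
        assert fit.a == pytest.approx(100.0, rel=1e-3)
        assert fit.x0 == pytest.approx(50.0, rel=1e-3)
        assert fit.b == pytest.approx(10.0, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_data_still_good_fit(self, rng):
        x = np.arange(0, 101, dtype=float)
        y = sigmoid(x, 100.0, 50.0, 10.0) + rng.normal(0, 1.0, x.size)
        fit = fit_sigmoid(x, y)
        assert fit.r_squared > 0.99

    def test_constant_y_flagged_degenerate(self):
        fit = fit_sigmoid([0.0, 1.0, 2.0, 3.0], [5.0] * 4)
        assert fit.degenerate and not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("p,stars", [
    (0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"),
])
def test_significance_star_mapping(p, stars):
    assert significance_stars(p) == stars
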