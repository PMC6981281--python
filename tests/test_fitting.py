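"""Grid-search fitting: objective, oracle equivalence, bootstrap."""

import itertools

import numpy as np
import pytest

from necrokinetics import (
    DeathModelParams,
    NoiseSpec,
    ParameterGrid,
    bootstrap_ci,
    detection_onset,
    fit_detection_anchored,
    fit_model,
    generate_necrosis_counts,
    predict_at,
    sse_objective,
)
from necrokinetics.model import active_necrosis_at


def exact_counts_tc(factory, params, times, n_fields=3):
    """Counts exactly equal to the (integer) model means."""
    means = [active_necrosis_at(params, t) for t in times]
    return factory(times, [[round(m)] * n_fields for m in means])


class TestObjective:
    def test_zero_on_exact_data(self, timecourse_factory):
        params = DeathModelParams(n0=40.0, r=0.5, period_days=31.0, onset_days=31.0)
        # means at 31 and 62 days are 20 and 10 exactly
        tc = timecourse_factory([31.0, 62.0], [[20, 20], [10, 10]])
        assert sse_objective(params, tc) == 0.0

    def test_hand_value(self, printed_params, timecourse_factory):
        """Means 4 and 3 vs model values at days 31 and 60."""
        tc = timecourse_factory([31.0, 60.0], [[4, 4], [3, 3]])
        m31 = active_necrosis_at(printed_params, 31.0)
        m60 = active_necrosis_at(printed_params, 60.0)
        expected = (4.0 - m31) ** 2 + (3.0 - m60) ** 2
        got = sse_objective(printed_params, tc)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.5726, abs=2e-4)

    def test_single_time_point_rejected(self, timecourse_factory):
        tc = timecourse_factory([31.0], [[4, 5]])
        with pytest.raises(ValueError):
            sse_objective(
                DeathModelParams(n0=30.0, r=0.1, period_days=31.0, onset_days=31.0),
                tc,
            )

    def test_field_weighting_option(self, printed_params, timecourse_factory):
        tc = timecourse_factory([31.0, 60.0], [[4, 4, 4], [3]])
        unweighted = sse_objective(printed_params, tc)
        weighted = sse_objective(printed_params, tc, weight_by_fields=True)
        m31 = active_necrosis_at(printed_params, 31.0)
        m60 = active_necrosis_at(printed_params, 60.0)
        assert weighted == pytest.approx(
            3 * (4.0 - m31) ** 2 + 1 * (3.0 - m60) ** 2, rel=1e-12
        )
        assert weighted != unweighted


def brute_force_fit(tc, grid):
    """Independent exhaustive re-evaluation over the full product grid."""
    best = None
    for r, p, onset, n0 in itertools.product(
        grid.r, grid.period_days, grid.onset_days, grid.n0
    ):
        params = DeathModelParams(
            n0=float(n0), r=float(r), period_days=float(p), onset_days=float(onset)
        )
        key = (sse_objective(params, tc), float(r), float(p), float(onset), float(n0))
        if best is None or key < best:
            best = key
    sse, r, p, onset, n0 = best
    return DeathModelParams(n0=n0, r=r, period_days=p, onset_days=onset), sse


class TestFitModel:
    def test_noiseless_grid_point_recovered(self, timecourse_factory):
        params = DeathModelParams(n0=40.0, r=0.5, period_days=31.0, onset_days=31.0)
        tc = timecourse_factory([31.0, 62.0, 93.0], [[20], [10], [5]])
        grid = ParameterGrid(
            n0=np.array([20.0, 40.0, 50.0]),
            r=np.array([0.25, 0.5, 0.75]),
            period_days=np.array([15.0, 31.0]),
            onset_days=np.array([0.0, 31.0]),
        )
        fit = fit_model(tc, grid)
        assert fit.params == params
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert not fit.degenerate

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_small_grids(self, seed, timecourse_factory):
        rng = np.random.default_rng(seed)
        times = [31.0, 92.0, 184.0, 368.0]
        counts = rng.poisson(rng.uniform(0.5, 5.0, size=4)[:, None], size=(4, 6))
        tc = timecourse_factory(times, counts.tolist())
        grid = ParameterGrid(
            n0=np.round(np.linspace(5, 60, 12), 6),
            r=np.round(np.linspace(0.02, 0.5, 9), 6),
            period_days=np.array([10.0, 31.0, 45.0, 62.0]),
            onset_days=np.array([0.0, 15.0, 31.0]),
        )
        assert grid.n_combinations <= 10_000
        fit = fit_model(tc, grid)
        bf_params, bf_sse = brute_force_fit(tc, grid)
        assert fit.params == bf_params
        assert fit.sse == pytest.approx(bf_sse, rel=1e-9, abs=1e-12)

    def test_all_zero_counts_flagged_degenerate(self, timecourse_factory):
        tc = timecourse_factory([31.0, 92.0], [[0, 0, 0], [0, 0, 0]])
        grid = ParameterGrid(
            n0=np.array([10.0, 20.0]),
            r=np.array([0.05, 0.1]),
            period_days=np.array([31.0]),
            onset_days=np.array([31.0]),
        )
        fit = fit_model(tc, grid)
        assert fit.degenerate
        assert fit.params.r == grid.r[0]

    def test_refinement_never_increases_sse(self, study_times):
        truth = DeathModelParams(n0=30.3, r=0.141, period_days=31.0, onset_days=31.0)
        tc = generate_necrosis_counts(truth, study_times, 30, NoiseSpec(), seed=5)
        grid_plain = ParameterGrid(
            n0=np.round(np.arange(10.0, 50.0, 1.0), 6),
            r=np.round(np.arange(0.05, 0.35, 0.01), 6),
            period_days=np.array([31.0]),
            onset_days=np.array([31.0]),
        )
        grid_refined = ParameterGrid(
            n0=grid_plain.n0, r=grid_plain.r,
            period_days=grid_plain.period_days,
            onset_days=grid_plain.onset_days, refine=True,
        )
        plain = fit_model(tc, grid_plain)
        refined = fit_model(tc, grid_refined)
        assert refined.sse <= plain.sse + 1e-15
        # refined parameters stay inside the grid hull
        assert grid_plain.n0[0] <= refined.params.n0 <= grid_plain.n0[-1]
        assert grid_plain.r[0] <= refined.params.r <= grid_plain.r[-1]


class TestPrediction:
    def test_printed_parameters_predict_day60(self, printed_params, study_times):
        tc = generate_necrosis_counts(printed_params, study_times, 5, seed=0)
        fit = fit_model(
            tc,
            ParameterGrid(
                n0=np.array([30.3]), r=np.array([0.141]),
                period_days=np.array([31.0]), onset_days=np.array([31.0]),
            ),
        )
        assert predict_at(fit, 60.0) == pytest.approx(3.706, abs=1e-3)
        assert predict_at(fit, 10.0) == 0.0
        assert predict_at(fit, 31.0) == pytest.approx(30.3 * 0.141, rel=1e-12)
        with pytest.raises(ValueError):
            predict_at(fit, -5.0)

    def test_prediction_consistent_with_fitted_curve(self, study_times):
        truth = DeathModelParams(n0=30.3, r=0.141, period_days=31.0, onset_days=31.0)
        tc = generate_necrosis_counts(truth, study_times, 20, seed=3)
        fit = fit_detection_anchored(tc)
        for t in study_times:
            assert predict_at(fit, t) == pytest.approx(
                fit.fitted_curve.loc[t], rel=1e-12
            )


class TestDetectionAnchored:
    def test_onset_is_first_positive_time(self, timecourse_factory):
        tc = timecourse_factory([15.0, 31.0, 62.0], [[0, 0], [4, 5], [3, 3]])
        assert detection_onset(tc) == 31.0
        fit = fit_detection_anchored(tc)
        assert fit.params.onset_days == 31.0
        assert fit.params.period_days == 31.0

    def test_all_zero_raises(self, timecourse_factory):
        tc = timecourse_factory([15.0, 31.0], [[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            detection_onset(tc)

    def test_bias_shrinks_with_more_fields(self, printed_params, study_times):
        """Median |r-hat - r| decreases from 30 to 300 fields per age."""
        errs = {30: [], 300: []}
        for n_fields in errs:
            for seed in range(5):
                tc = generate_necrosis_counts(
                    printed_params, study_times, n_fields, seed=100 + seed
                )
                fit = fit_detection_anchored(tc)
                errs[n_fields].append(abs(fit.params.r - printed_params.r))
        assert np.median(errs[300]) < np.median(errs[30])


class TestBootstrap:
    def make_grid(self):
        return ParameterGrid(
            n0=np.round(np.arange(15.0, 45.0, 0.5), 6),
            r=np.round(np.arange(0.05, 0.30, 0.005), 6),
            period_days=np.array([31.0]),
            onset_days=np.array([31.0]),
        )

    def test_seeded_reproducibility(self, printed_params, study_times):
        tc = generate_necrosis_counts(printed_params, study_times, 30, seed=11)
        grid = self.make_grid()
        a = bootstrap_ci(tc, grid, B=40, seed=7)
        b = bootstrap_ci(tc, grid, B=40, seed=7)
        assert a.intervals == b.intervals
        assert (a.samples == b.samples).all().all()

    def test_single_replicate_degenerate_interval(self, printed_params, study_times):
        tc = generate_necrosis_counts(printed_params, study_times, 30, seed=11)
        ci = bootstrap_ci(tc, self.make_grid(), B=1, seed=0)
        for lo, hi in ci.intervals.values():
            assert lo == hi

    def test_invalid_arguments(self, printed_params, study_times):
        tc = generate_necrosis_counts(printed_params, study_times, 30, seed=11)
        with pytest.raises(ValueError):
            bootstrap_ci(tc, self.make_grid(), B=0)
        with pytest.raises(ValueError):
            bootstrap_ci(tc, self.make_grid(), B=10, level=1.5)

    def test_interval_order_and_point_containment(
        self, printed_params, study_times
    ):
        tc = generate_necrosis_counts(printed_params, study_times, 30, seed=11)
        ci = bootstrap_ci(tc, self.make_grid(), B=100, seed=3)
        for lo, hi in ci.intervals.values():
            assert lo <= hi


class TestGridValidation:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            ParameterGrid(
                n0=np.array([5.0, 4.0]), r=np.array([0.1]),
                period_days=np.array([31.0]), onset_days=np.array([0.0]),
            )
        with pytest.raises(ValueError):
            ParameterGrid(
                n0=np.array([5.0]), r=np.array([1.2]),
                period_days=np.array([31.0]), onset_days=np.array([0.0]),
            )
        with pytest.raises(ValueError):
            ParameterGrid(
                n0=np.array([]), r=np.array([0.1]),
                period_days=np.array([31.0]), onset_days=np.array([0.0]),
            )

    def test_default_grid_shape(self):
        g = ParameterGrid.default()
        assert g.n0[0] == 5.0 and g.n0[-1] == 60.0
        assert g.r[0] == 0.01 and g.r[-1] == 0.6
        assert g.n_combinations == 551 * 591 * 86 * 91
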