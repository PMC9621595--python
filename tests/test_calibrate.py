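"""Tests of SEM correction, the weighted cost, the chi-square gate and the
annealing machinery."""

import numpy as np
import pandas as pd
import pytest

from isletchip import (AnnealSchedule, CalibrationProblem, ModelParameters,
                       OffsetParameters, TimeSeriesDataset, anneal,
                       chi2_threshold, correct_sem, cost, fit_insulin_decay,
                       uncertainty_envelope, standard_protocol)
from isletchip.calibrate import result_accepted_entries
from isletchip.synthetic import SyntheticExperimentSpec, generate_experiment


def dataset_from(means, sems, times=None, observable="glucose"):
    n = len(means)
    times = times if times is not None else [32.0 + 8 * i for i in range(n)]
    return TimeSeriesDataset(pd.DataFrame(dict(
        series_id=["s"] * n, observable=[observable] * n,
        culture_type=["co-culture"] * n, regime=["hyper"] * n,
        gtt=["d1"] * n, time_h=times, mean=means, sem=sems, n=[5] * n)))


class TestCorrectSem:
    def test_single_low_point_gets_dataset_max(self):
        ds = correct_sem(dataset_from([2.0, 10.0, 2.0], [0.1, 0.5, 0.02]))
        # 0.1 is exactly 5% of 2 -> not "below"; only the third is replaced
        assert list(ds.table["sem"]) == [0.1, 0.5, 0.5]

    def test_all_low_falls_back_to_ten_percent(self):
        ds = correct_sem(dataset_from([10.0, 20.0], [0.1, 0.2]))
        assert list(ds.table["sem"]) == [1.0, 2.0]

    def test_healthy_sems_unchanged(self):
        ds = correct_sem(dataset_from([10.0], [1.0]))
        assert list(ds.table["sem"]) == [1.0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            TimeSeriesDataset(pd.DataFrame(columns=[
                "series_id", "observable", "culture_type", "regime", "gtt",
                "time_h", "mean", "sem", "n"]))

    def test_csv_round_trip(self, tmp_path):
        ds = dataset_from([7.45, 8.77], [0.63, 0.74])
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = TimeSeriesDataset.from_csv(path)
        pd.testing.assert_frame_equal(ds.table, back.table)


class TestChi2Threshold:
    @pytest.mark.parametrize("df, expected", [
        (20, 31.41), (7, 14.07), (1, 3.841)])
    def test_printed_quantiles(self, df, expected):
        assert chi2_threshold(0.05, df) == pytest.approx(expected, abs=5e-3)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            chi2_threshold(0.05, 0)


class TestCost:
    def test_perfect_fit_is_zero_and_hand_value(self, config, params):
        spec = SyntheticExperimentSpec(noise_cv=0.0, regimes=("hyper",))
        ds = generate_experiment(spec, config)
        # noiseless data generated by the model itself: near-zero cost
        # (residual is only the generation-vs-evaluation step-size gap)
        table = ds.table.copy()
        table["sem"] = 0.1 * table["mean"]
        problem = CalibrationProblem(TimeSeriesDataset(table), config,
                                     base_params=params, free=("E_G0",))
        V = cost(params, OffsetParameters(), problem)
        assert V == pytest.approx(0.0, abs=1e-4)

    def test_hand_evaluated_residuals(self, monkeypatch, config, params):
        ds = dataset_from([10.0, 8.0], [1.0, 0.5])
        problem = CalibrationProblem(ds, config, base_params=params,
                                     free=("E_G0",))
        from isletchip import calibrate as cal

        fake = {("co-culture:hyper", "glucose", 32.0): 9.0,
                ("co-culture:hyper", "glucose", 40.0): 9.0}
        monkeypatch.setattr(cal, "_predictions", lambda *a, **k: fake)
        V = cost(params, OffsetParameters(), problem)
        assert V == pytest.approx(1.0 / 1.0 + 1.0 / 0.25)

    def test_doubling_sem_quarters_cost(self, monkeypatch, config, params):
        from isletchip import calibrate as cal

        fake = {("co-culture:hyper", "glucose", 32.0): 9.0,
                ("co-culture:hyper", "glucose", 40.0): 9.0}
        monkeypatch.setattr(cal, "_predictions", lambda *a, **k: fake)
        V1 = cost(params, OffsetParameters(),
                  CalibrationProblem(dataset_from([10, 8], [1.0, 0.5]),
                                     config, params, free=("E_G0",)))
        V2 = cost(params, OffsetParameters(),
                  CalibrationProblem(dataset_from([10, 8], [2.0, 1.0]),
                                     config, params, free=("E_G0",)))
        assert V1 == pytest.approx(4.0 * V2)

    def test_invariant_to_row_order(self, config, params):
        spec = SyntheticExperimentSpec(noise_cv=0.05, seed=3)
        ds = correct_sem(generate_experiment(spec, config))
        shuffled = TimeSeriesDataset(
            ds.table.sample(frac=1.0, random_state=0).reset_index(drop=True))
        p1 = CalibrationProblem(ds, config, params, free=("E_G0",))
        p2 = CalibrationProblem(shuffled, config, params, free=("E_G0",))
        assert cost(params, OffsetParameters(), p1) == pytest.approx(
            cost(params, OffsetParameters(), p2))


class _QuadraticProblem:
    """1-D convex sanity stand-in exposing the calibration interface."""

    labels = ["x"]
    n_points = 5  # threshold chi2(0.95, 5) ~ 11.07

    def search_bounds(self):
        return np.array([0.0]), np.array([10.0])

    def from_search(self, z):
        return np.array(z, dtype=float)

    def decode(self, x):
        return float(x[0]), {}

    def evaluate(self, x):
        return float((x[0] - 3.0) ** 2)


class TestAnneal:
    def test_convex_sanity(self):
        result = anneal(_QuadraticProblem(), seed=0,
                        schedule=AnnealSchedule(n_iter=2000, n_restarts=2,
                                                polish=True))
        assert result.p_opt["x"] == pytest.approx(3.0, abs=0.01)
        assert result.passed

    def test_same_seed_reproduces_accepted_list(self):
        s = AnnealSchedule(n_iter=500, n_restarts=1, polish=False)
        r1 = anneal(_QuadraticProblem(), seed=11, schedule=s)
        r2 = anneal(_QuadraticProblem(), seed=11, schedule=s)
        pd.testing.assert_frame_equal(r1.accepted, r2.accepted)
        assert r1.V_opt == r2.V_opt

    def test_accepted_all_below_threshold(self):
        r = anneal(_QuadraticProblem(), seed=2,
                   schedule=AnnealSchedule(n_iter=500, n_restarts=1,
                                           polish=False))
        assert (r.accepted["V"] < r.threshold).all()
        assert r.V_opt == pytest.approx(r.accepted["V"].min(), abs=1e-12)

    def test_self_consistency_on_synthetic_data(self, config):
        spec = SyntheticExperimentSpec(noise_cv=0.05, seed=5,
                                       regimes=("hyper",))
        ds = correct_sem(generate_experiment(spec, config))
        problem = CalibrationProblem(
            ds, config, base_params=spec.true_params, free=("E_G0",),
            bounds={"E_G0": (0.5, 4.0)})
        result = anneal(problem, seed=1,
                        schedule=AnnealSchedule(n_iter=300, n_restarts=1))
        assert result.passed
        assert result.p_opt["E_G0"] == pytest.approx(1.47, rel=0.1)


class TestChi2Coherence:
    def test_pass_rate_near_95_percent(self, config, params):
        """Data drawn from the model with exactly-known SEM should pass the
        chi-square gate at ~95% over repeated draws."""
        import dataclasses

        spec = SyntheticExperimentSpec(noise_cv=0.05, regimes=("hyper",),
                                       sem_mode="exact")
        passes = 0
        n_draws = 100
        for i in range(n_draws):
            ds = generate_experiment(dataclasses.replace(spec, seed=1000 + i),
                                     config)
            problem = CalibrationProblem(ds, config, base_params=params,
                                         free=("E_G0",))
            V = cost(params, OffsetParameters(), problem)
            passes += V < chi2_threshold(0.05, ds.n_points)
        assert 0.90 <= passes / n_draws <= 1.0


class TestEnvelope:
    def test_single_vector_gives_zero_width(self, config, params):
        proto = standard_protocol("hyper", gtt_days=(1,), config=config)
        bands = uncertainty_envelope([params], config, proto)
        assert np.allclose(bands.width("G_pooled"), 0.0)

    def test_adding_vector_never_shrinks_bands(self, config, params):
        proto = standard_protocol("hyper", gtt_days=(1,), config=config)
        b1 = uncertainty_envelope([params], config, proto)
        b2 = uncertainty_envelope([params, params.replace(E_G0=2.0)],
                                  config, proto)
        for var in ("G_pooled", "I_pooled", "S_I", "V_beta"):
            assert np.all(b2.width(var) >= b1.width(var) - 1e-12)
            assert np.all(b2.lo[var] <= b1.lo[var] + 1e-12)
            assert np.all(b2.hi[var] >= b1.hi[var] - 1e-12)

    def test_result_entries_decode(self, config):
        spec = SyntheticExperimentSpec(noise_cv=0.05, seed=5,
                                       regimes=("hyper",))
        ds = correct_sem(generate_experiment(spec, config))
        problem = CalibrationProblem(ds, config, spec.true_params,
                                     free=("E_G0",),
                                     bounds={"E_G0": (0.5, 4.0)})
        result = anneal(problem, seed=1,
                        schedule=AnnealSchedule(n_iter=200, n_restarts=1))
        entries = result_accepted_entries(result, problem)
        assert entries and isinstance(entries[0][0], ModelParameters)


class TestInsulinDecayFit:
    def test_exact_exponential(self):
        t = np.array([0.0, 8.0, 24.0, 48.0])
        c = 100.0 * np.exp(-0.024 * t)
        assert fit_insulin_decay(t, c) == pytest.approx(0.024)

    def test_two_points(self):
        assert fit_insulin_decay([0.0, 24.0], [100.0, 56.23]) == pytest.approx(
            0.024, abs=1e-4)

    def test_constant_series(self):
        assert fit_insulin_decay([0, 10, 20], [5.0, 5.0, 5.0]) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_insulin_decay([0.0], [1.0])
        with pytest.raises(ValueError):
            fit_insulin_decay([0.0, 1.0], [1.0, 0.0])
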