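"""Forward chaining, fold assignment, scoring rules and curves."""

import numpy as np
import pandas as pd
import pytest

from eczema_ssm import (
    SimulationConfig,
    TruncatedNormalMixture,
    draw_true_parameters,
    forward_chain_evaluate,
    horizon_curve,
    learning_curve,
    lpd_score,
    make_folds,
    rmse_score,
    simulate_dataset,
)
from eczema_ssm.data import N_GRID
from eczema_ssm.validation import RECORD_COLUMNS


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_patients=8, n_biomarkers=2, seed=17)
    ds, _ = simulate_dataset(draw_true_parameters(cfg), cfg)
    return ds


@pytest.fixture(scope="module")
def uniform_records(cohort):
    folds = make_folds(cohort, 4, seed=5)
    return forward_chain_evaluate("uniform", cohort, folds)


class TestFolds:
    def test_partition_and_balance(self, cohort):
        folds = make_folds(cohort, 3, seed=1)
        all_pids = sorted(p for f in range(3) for p in folds.fold_patients(f))
        assert all_pids == sorted(cohort.patient_ids)
        sizes = [len(folds.fold_patients(f)) for f in range(3)]
        assert max(sizes) - min(sizes) <= 1

    def test_seven_folds_of_six_at_study_size(self):
        cfg = SimulationConfig(n_patients=42, n_biomarkers=2, seed=2)
        ds, _ = simulate_dataset(draw_true_parameters(cfg), cfg)
        folds = make_folds(ds, 7, seed=0)
        assert all(len(folds.fold_patients(f)) == 6 for f in range(7))

    def test_determinism_and_validation(self, cohort):
        a1 = make_folds(cohort, 3, seed=9).assignment
        a2 = make_folds(cohort, 3, seed=9).assignment
        assert a1 == a2
        with pytest.raises(ValueError):
            make_folds(cohort, 99, seed=0)


class TestForwardChaining:
    def test_each_later_visit_scored_once(self, cohort, uniform_records):
        rec = uniform_records
        expected = sum(
            cohort.grid.observed_times(k).size - 1
            for k in range(cohort.n_patients)
        )
        assert len(rec) == expected
        keys = rec[["patient_id", "target_week"]].apply(tuple, axis=1)
        assert keys.is_unique

    def test_uniform_lpd_closed_form(self, uniform_records):
        assert np.allclose(uniform_records["lpd"], -np.log(72.0))

    def test_horizon_sequence_full_schedule(self, uniform_records, cohort):
        pid = cohort.patient_ids[0]  # fully observed: 6 visits -> 5 targets
        sub = uniform_records[uniform_records["patient_id"] == pid]
        sub = sub.sort_values("target_week")
        assert list(sub["horizon"]) == [1, 1, 2, 2, 6]
        assert list(sub["target_week"]) == [2, 4, 8, 12, 24]
        assert list(sub["n_train_visits"]) == [1, 2, 3, 4, 5]

    def test_no_future_leakage_in_revealed_data(self, cohort):
        revealed = cohort.reveal_visits([0, 1], n_visits=2)
        for k in (0, 1):
            assert revealed.grid.observed_times(k).size == 2
            t_full = cohort.grid.observed_times(k)
            np.testing.assert_array_equal(
                revealed.grid.observed_times(k), t_full[:2]
            )
        # non-test patients untouched
        assert revealed.grid.observed_times(2).size == cohort.grid.observed_times(2).size

    def test_record_schema(self, uniform_records):
        assert list(uniform_records.columns) == RECORD_COLUMNS


class TestScoring:
    def test_lpd_gaussian_closed_form(self):
        # wide bounds make the truncated component effectively Gaussian
        pred = TruncatedNormalMixture([500.0], [1.0], 0.0, 1000.0)
        assert lpd_score(pred, 500.0) == pytest.approx(-0.9189385, abs=1e-6)

    def test_lpd_converges_with_draws(self):
        # mixture of many identical components equals the single component
        rng = np.random.default_rng(0)
        locs = np.full(4000, 30.0)
        pred = TruncatedNormalMixture(locs, np.full(4000, 2.0), 0.0, 72.0)
        single = TruncatedNormalMixture([30.0], [2.0], 0.0, 72.0)
        assert pred.logpdf(31.0) == pytest.approx(single.logpdf(31.0), abs=1e-12)

    def test_rmse_hand_example(self):
        rec = pd.DataFrame({
            "patient_id": ["a", "b"],
            "sq_err": [9.0, 16.0],
        })
        rmse, se = rmse_score(rec, n_boot=200, seed=1)
        assert rmse == pytest.approx(np.sqrt(12.5), abs=1e-12)
        assert se > 0

    def test_rmse_perfect_predictions(self):
        rec = pd.DataFrame({"patient_id": ["a", "a"], "sq_err": [0.0, 0.0]})
        assert rmse_score(rec, n_boot=10)[0] == 0.0
        with pytest.raises(ValueError):
            rmse_score(rec.iloc[:0])


class TestCurves:
    def test_uniform_curves_flat(self, uniform_records):
        lc = learning_curve(uniform_records, horizon_adjustment="none")
        assert np.allclose(lc["mean_lpd"], -np.log(72.0))
        hc = horizon_curve(uniform_records)
        assert np.allclose(hc["mean_lpd"], -np.log(72.0))
        assert set(hc["horizon"]) == {1, 2, 6}

    def test_restriction_to_one_step_targets(self, uniform_records):
        lc = learning_curve(uniform_records, horizon_adjustment="restrict")
        # one-step targets exist only for the first two chaining steps
        assert set(lc["n_train_visits"]) <= {1, 2}

    def test_rw_lpd_decays_with_horizon(self):
        # on random-walk data the predictive variance grows with h
        rng = np.random.default_rng(3)
        values = np.full((20, N_GRID), np.nan)
        walk = 36.0 + np.cumsum(2.0 * rng.standard_normal((20, N_GRID)), axis=1)
        for t in (0, 1, 2, 4, 6, 12):
            values[:, t] = np.clip(walk[:, t], 0, 72)
        from eczema_ssm import LongitudinalDataset, ObservationGrid, PatientRecord, get_scale

        scale = get_scale("EASI")
        ds = LongitudinalDataset(
            scale=scale,
            patients=[PatientRecord(f"P{i}", np.zeros(1), ["c"]) for i in range(20)],
            grid=ObservationGrid(values, scale),
        )
        rec = forward_chain_evaluate("rw", ds, make_folds(ds, 4, seed=2))
        hc = horizon_curve(rec).set_index("horizon")
        assert hc.loc[1, "mean_lpd"] > hc.loc[6, "mean_lpd"]
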