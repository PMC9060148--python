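"""Domain types, preprocessing and grid/file I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eczema_ssm import (
    STRUCTURAL_MISSING_WEEKS,
    align_to_grid,
    get_scale,
    load_dataset,
    preprocess_covariates,
    read_dataset,
    write_dataset,
)
from eczema_ssm.data import N_GRID, week_to_index


class TestScales:
    @pytest.mark.parametrize(
        "name,maximum",
        [("EASI", 72), ("oSCORAD", 83), ("SCORAD", 103), ("POEM", 28)],
    )
    def test_registered_maxima(self, name, maximum):
        assert get_scale(name).max_score == maximum

    def test_bounds_validation(self):
        easi = get_scale("EASI")
        easi.validate_value(72.0)
        with pytest.raises(ValueError):
            easi.validate_value(80.0)
        with pytest.raises(KeyError):
            get_scale("NRS")


class TestLoading:
    def test_toy_dataset_grid_shape(self, toy_csvs):
        ds = load_dataset(*toy_csvs, "EASI")
        assert ds.n_patients == 2
        assert ds.grid.values.shape == (2, N_GRID)
        # 2 visits observed -> 11 of 13 grid cells missing per patient
        assert (ds.grid.missing_mask.sum(axis=1) == 11).all()
        assert ds.n_covariates == 6  # 2 biomarkers + FLG/treatment/sex/age

    def test_out_of_bounds_value_rejected(self, toy_csvs, tmp_path):
        sev_path, cov_path = toy_csvs
        sev = pd.read_csv(sev_path)
        sev.loc[0, "value"] = 80.0  # > 72, the EASI maximum
        bad = tmp_path / "bad.csv"
        sev.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="outside"):
            load_dataset(bad, cov_path, "EASI")

    def test_off_grid_week_rejected(self, toy_csvs, tmp_path):
        sev_path, cov_path = toy_csvs
        sev = pd.read_csv(sev_path)
        sev.loc[0, "week"] = 3
        bad = tmp_path / "bad.csv"
        sev.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="off the 2-week grid"):
            load_dataset(bad, cov_path, "EASI")

    def test_duplicate_observation_rejected(self, toy_csvs, tmp_path):
        sev_path, cov_path = toy_csvs
        sev = pd.read_csv(sev_path)
        sev.loc[1, "week"] = 0  # duplicates (p1, week 0)
        bad = tmp_path / "bad.csv"
        sev.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_dataset(bad, cov_path, "EASI")

    def test_missing_column_rejected(self, toy_csvs, tmp_path):
        sev_path, cov_path = toy_csvs
        sev = pd.read_csv(sev_path).drop(columns=["value"])
        bad = tmp_path / "bad.csv"
        sev.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="lacks columns"):
            load_dataset(bad, cov_path, "EASI")

    def test_round_trip(self, toy_csvs, tmp_path):
        ds = load_dataset(*toy_csvs, "EASI")
        write_dataset(ds, tmp_path / "out")
        ds2 = read_dataset(tmp_path / "out")
        np.testing.assert_array_equal(ds.grid.values, ds2.grid.values)
        np.testing.assert_array_equal(ds.covariate_matrix, ds2.covariate_matrix)
        assert ds.patient_ids == ds2.patient_ids


class TestPreprocessing:
    def _demographics(self, n):
        rng = np.random.default_rng(0)
        return dict(
            flg_status=pd.Series(np.zeros(n)),
            treatment=pd.Series(np.ones(n)),
            sex=pd.Series(np.zeros(n)),
            age=pd.Series(rng.normal(40, 10, n)),
        )

    def test_log_then_zscore_hand_example(self):
        # [1, e, e^2] -> log -> [0, 1, 2] -> z-score (sample SD = 1) -> [-1, 0, 1]
        bm = pd.DataFrame({"x": [1.0, np.e, np.e**2]})
        matrix, names, _ = preprocess_covariates(bm, **self._demographics(3))
        np.testing.assert_allclose(matrix[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_missing_biomarker_imputed_to_zero(self):
        bm = pd.DataFrame({"x": [1.0, 2.0, 4.0, np.nan]})
        matrix, _, tr = preprocess_covariates(bm, **self._demographics(4))
        assert matrix[3, 0] == 0.0
        assert tr.n_imputed_biomarkers == 1

    def test_missing_flg_defaults_to_no_mutation(self):
        bm = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        dem = self._demographics(3)
        dem["flg_status"] = pd.Series([1.0, np.nan, np.nan])
        matrix, names, tr = preprocess_covariates(bm, **dem)
        j = names.index("FLG")
        np.testing.assert_array_equal(matrix[:, j], [1.0, 0.0, 0.0])
        assert tr.n_imputed_flg == 2

    def test_degenerate_and_nonpositive_columns_rejected(self):
        dem = self._demographics(3)
        with pytest.raises(ValueError, match="degenerate"):
            preprocess_covariates(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), **dem)
        with pytest.raises(ValueError, match="non-positive"):
            preprocess_covariates(pd.DataFrame({"x": [1.0, -1.0, 2.0]}), **dem)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=3, max_size=30),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_zscore_moments_property(self, values, seed):
        # any non-degenerate biomarker column ends with mean 0, sample var 1
        rng = np.random.default_rng(seed)
        col = np.asarray(values) * (1 + 0.1 * rng.random(len(values)))
        if np.ptp(np.log(col)) < 1e-6:
            return
        bm = pd.DataFrame({"x": col})
        matrix, _, _ = preprocess_covariates(bm, **self._demographics(len(col)))
        assert abs(matrix[:, 0].mean()) < 1e-10
        assert abs(matrix[:, 0].var(ddof=1) - 1.0) < 1e-10


class TestGridAlignment:
    def _long(self, weeks, pid="p1"):
        return pd.DataFrame(
            {"patient_id": pid, "week": list(weeks), "value": 10.0}
        )

    def test_full_schedule_missingness(self):
        grid = align_to_grid(self._long([0, 2, 4, 8, 12, 24]), ["p1"], get_scale("EASI"))
        assert grid.missing_mask.sum() == 7
        assert grid.missing_fraction == pytest.approx(7 / 13)
        missing_weeks = {2 * t for t in np.flatnonzero(grid.missing_mask[0])}
        assert missing_weeks == set(STRUCTURAL_MISSING_WEEKS)

    def test_missed_final_visit(self):
        grid = align_to_grid(self._long([0, 2, 4, 8, 12]), ["p1"], get_scale("EASI"))
        assert grid.missing_mask.sum() == 8

    def test_odd_week_rejected(self):
        with pytest.raises(ValueError):
            week_to_index(3)
        with pytest.raises(ValueError):
            align_to_grid(self._long([0, 3]), ["p1"], get_scale("EASI"))
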