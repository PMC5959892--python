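"""Preprocessing: lock-mass correction, background subtraction, binning, TIC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iknife import (
    BinGrid, SyntheticConfig, generate_cohort, build_feature_matrix,
    lock_mass_correct, subtract_background, bin_spectrum, normalize_tic,
)
from iknife.synthetic import noiseless

from conftest import make_record


class TestLockMass:
    def test_observed_offset_is_subtracted_everywhere(self):
        rec = make_record([650.0, 699.520, 900.0], [5.0, 100.0, 2.0])
        corrected, shift = lock_mass_correct(rec, reference=699.497, search_window=0.3)
        assert shift == pytest.approx(0.023)
        np.testing.assert_allclose(corrected.mz, [650.0 - 0.023, 699.497, 900.0 - 0.023])
        np.testing.assert_array_equal(corrected.intensity, rec.intensity)

    def test_exact_lock_peak_is_identity(self):
        rec = make_record([650.0, 699.497], [5.0, 100.0])
        corrected, shift = lock_mass_correct(rec, 699.497, 0.3)
        assert shift == 0.0
        np.testing.assert_array_equal(corrected.mz, rec.mz)

    def test_absent_lock_peak_warns_and_leaves_unchanged(self, caplog):
        rec = make_record([650.0, 900.0], [5.0, 2.0])
        with caplog.at_level("WARNING"):
            corrected, shift = lock_mass_correct(rec, 699.497, 0.3)
        assert shift is None
        assert corrected is rec
        assert "lock-mass" in caplog.text

    def test_correction_undoes_simulated_drift_exactly(self):
        """Generator round trip: +0.05 Da drift is recovered to 1e-9."""
        cfg = dataclasses.replace(noiseless(SyntheticConfig(seed=5)), drift_sd=0.0)
        reference = generate_cohort(cfg).records[0]
        drifted = reference.replace_peaks(reference.mz + 0.05, reference.intensity)
        corrected, shift = lock_mass_correct(drifted, cfg.lock_mass, 0.3)
        assert shift == pytest.approx(0.05, abs=1e-9)
        np.testing.assert_allclose(corrected.mz, reference.mz, atol=1e-9)

    def test_idempotent(self):
        rec = make_record([650.0, 699.520, 900.0], [5.0, 100.0, 2.0])
        once, _ = lock_mass_correct(rec, 699.497, 0.3)
        twice, second_shift = lock_mass_correct(once, 699.497, 0.3)
        assert second_shift == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(twice.mz, once.mz, atol=1e-12)


class TestBackground:
    def test_flat_spectrum_fully_removed(self):
        rec = make_record([650.0, 700.0, 750.0], [5.0, 5.0, 5.0])
        assert subtract_background(rec, 0.05).n_peaks == 0

    def test_zero_baseline_is_identity(self):
        rec = make_record([650.0, 700.0], [0.0, 5.0])
        out = subtract_background(rec, 0.0)  # 0th quantile = 0 after the zero peak
        np.testing.assert_array_equal(out.intensity, [5.0])

    def test_matches_naive_quantile_subtraction(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(600, 1000, 50))
        inten = rng.exponential(10.0, 50)
        rec = make_record(mz, inten)
        out = subtract_background(rec, 0.05)
        baseline = np.quantile(inten, 0.05)
        expect = np.clip(inten - baseline, 0, None)
        keep = expect > 0
        np.testing.assert_allclose(out.mz, mz[keep])
        np.testing.assert_allclose(out.intensity, expect[keep])


class TestBinning:
    def test_single_peak_lands_in_its_bin(self):
        grid = BinGrid()
        vec = bin_spectrum(make_record([699.497], [10.0]), grid)
        assert vec.sum() == 10.0
        assert vec[np.flatnonzero(vec)[0]] == 10.0
        assert grid.labels[np.flatnonzero(vec)[0]] == pytest.approx(699.4)

    def test_half_open_edges(self):
        grid = BinGrid()
        vec = bin_spectrum(make_record([700.0499, 700.0501, 700.1000], [5.0, 5.0, 5.0]), grid)
        labels = grid.labels
        assert vec[np.flatnonzero(np.isclose(labels, 700.0))[0]] == 10.0
        assert vec[np.flatnonzero(np.isclose(labels, 700.1))[0]] == 5.0

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(550, 1050, 1000))
        mz = mz[np.diff(mz, prepend=-1) > 0]
        inten = rng.exponential(5.0, mz.size)
        grid = BinGrid()
        vec = bin_spectrum(make_record(mz, inten), grid)
        brute = np.zeros(grid.n_bins)
        for m, i in zip(mz, inten):
            j = int(np.floor((m - grid.lower) / grid.width + 1e-6))
            if 0 <= j < grid.n_bins:
                brute[j] += i
        np.testing.assert_array_equal(vec, brute)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.floats(600.0, 999.95), st.floats(0.0, 1e4)),
                    min_size=1, max_size=40))
    def test_binning_conserves_in_window_intensity(self, peaks):
        mz = np.array(sorted({round(m, 4) for m, _ in peaks}))
        inten = np.abs(np.array([i for _, i in peaks[: mz.size]]))
        vec = bin_spectrum(make_record(mz, inten), BinGrid())
        assert vec.sum() == pytest.approx(inten.sum(), rel=1e-12, abs=1e-9)

    def test_grid_must_divide_evenly(self):
        with pytest.raises(ValueError):
            BinGrid(lower=600.0, upper=1000.05, width=0.1)

    def test_default_grid_has_4000_bins(self):
        assert BinGrid().n_bins == 4000


class TestNormalize:
    def test_example_vector(self):
        # signal floor lifted: this checks the arithmetic, not the QC rule
        out, reject = normalize_tic(np.array([2.0, 2.0, 0.0, 4.0]), signal_floor=0.0)
        assert not reject
        np.testing.assert_allclose(out, [0.25, 0.25, 0.0, 0.5])

    def test_all_zero_vector_is_qc_rejected(self):
        _, reject = normalize_tic(np.zeros(10))
        assert reject

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=50))
    def test_output_sums_to_one_when_accepted(self, values):
        out, reject = normalize_tic(np.array(values))
        if not reject:
            assert out.sum() == pytest.approx(1.0, abs=1e-9)


class TestFeatureMatrix:
    def test_default_grid_gives_4000_columns(self, default_matrix):
        assert default_matrix.intensities.shape[1] == 4000

    def test_rows_sum_to_one(self, default_matrix):
        np.testing.assert_allclose(default_matrix.values().sum(axis=1), 1.0, atol=1e-9)

    def test_noiseless_cohort_rows_identical_within_class(self, noiseless_cohort):
        matrix = build_feature_matrix(noiseless_cohort)
        for cls in matrix.classes:
            rows = matrix.values()[(matrix.metadata["tissue_class"] == cls).to_numpy()]
            assert np.allclose(rows, rows[0], atol=1e-12)

    def test_empty_spectrum_dropped_and_logged(self, small_cohort, caplog):
        from iknife import CohortTable
        weak = make_record([650.0], [1.0], burn="WEAK", patient="PX", sample="SX")
        cohort = CohortTable(records=small_cohort.records + [weak])
        with caplog.at_level("WARNING"):
            matrix = build_feature_matrix(cohort)
        assert "WEAK" in matrix.rejected
        assert "WEAK" not in matrix.intensities.index
        assert "WEAK" in caplog.text

    def test_row_order_does_not_change_values(self, small_cohort):
        from iknife import CohortTable
        forward = build_feature_matrix(small_cohort)
        reversed_cohort = CohortTable(records=list(reversed(small_cohort.records)))
        backward = build_feature_matrix(reversed_cohort)
        shared = forward.intensities.index
        np.testing.assert_allclose(forward.intensities.loc[shared].to_numpy(),
                                   backward.intensities.loc[shared].to_numpy(),
                                   atol=1e-12)

    def test_csv_export_has_one_decimal_bin_labels(self, small_cohort, tmp_path):
        matrix = build_feature_matrix(small_cohort)
        out = tmp_path / "matrix.csv"
        matrix.to_csv(out)
        header = out.read_text().splitlines()[0].split(",")
        assert header[-1] == "999.9" and "600.0" in header
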