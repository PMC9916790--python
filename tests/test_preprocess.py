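"""Preprocessing chain: TopHat, TIC, denoising, peak picking, extraction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thyromsi import msi_data as md
from thyromsi import preprocess as pp
from thyromsi import synthetic_msi as synth
from thyromsi.errors import DataError, ParameterError

from conftest import noise_free_single_peptide_config


class TestTopHat:
    def test_constant_spectrum_removed_entirely(self):
        out = pp.tophat_baseline(np.array([5.0, 5, 5, 5, 5]), width=3)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_hand_computed_opening(self):
        # erosion of [2,2,12,2,2] with width 3 -> [2,2,2,2,2]; dilation back
        # -> [2,2,2,2,2]; the narrow peak survives the subtraction
        out = pp.tophat_baseline(np.array([2.0, 2, 12, 2, 2]), width=3)
        np.testing.assert_array_equal(out, [0, 0, 10, 0, 0])

    @given(
        st.lists(st.floats(0, 1e4), min_size=5, max_size=60),
        st.floats(-100, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_to_added_constant(self, values, c):
        f = np.array(values)
        np.testing.assert_allclose(
            pp.tophat_baseline(f + c, 5), pp.tophat_baseline(f, 5), atol=1e-9
        )

    @given(st.lists(st.floats(0, 1e4), min_size=7, max_size=80))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antiextensive_and_nonnegative(self, values):
        f = np.array(values)
        out = pp.tophat_baseline(f, 7)
        assert np.all(out >= -1e-12)
        assert np.all(out <= f + 1e-12)

    @pytest.mark.parametrize("width", [2, 1, -3, 101])
    def test_bad_width_rejected(self, width):
        with pytest.raises(ParameterError):
            pp.tophat_baseline(np.zeros(10), width)


class TestTICNormalize:
    @staticmethod
    def _ds(rows):
        mz = 700.0 + 0.5 * np.arange(len(rows[0]))
        return md.MSIDataset.from_matrix(
            [(i, 0) for i in range(len(rows))], mz, np.array(rows, dtype=float)
        )

    def test_worked_example(self):
        out = pp.tic_normalize(self._ds([[1.0, 2, 3, 4]]), target=1.0)
        np.testing.assert_allclose(out.spectra[0][1], [0.1, 0.2, 0.3, 0.4])

    def test_idempotent_on_normalized_input(self):
        once = pp.tic_normalize(self._ds([[1.0, 2, 3, 4], [8, 4, 2, 2]]), 10.0)
        twice = pp.tic_normalize(once, 10.0)
        for (_, a), (_, b) in zip(once.spectra, twice.spectra):
            np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_sum_pixel_identified(self):
        with pytest.raises(DataError, match=r"\(1,0\)"):
            pp.tic_normalize(self._ds([[1.0, 2, 3, 4], [0, 0, 0, 0]]), 1.0)

    def test_sums_conserved_on_synthetic_cube(self, default_sim):
        """Per-pixel TIC equals the target to 1e-9 relative after correction
        of the planted CV-0.2 pixel-to-pixel variation."""
        _cfg, ds, _roi, _truth = default_sim
        out = pp.tic_normalize(pp.tophat_dataset(ds), target=1000.0)
        sums = np.array([s.sum() for _, s in out.spectra])
        np.testing.assert_allclose(sums, 1000.0, rtol=1e-9)


class TestSpatialDenoise:
    @staticmethod
    def _fm(values, w, h):
        return pp.FeatureMatrix(
            feature_mz=np.array([1000.0]),
            values=np.asarray(values, float).reshape(-1, 1),
            pixel_index=[(x, y) for y in range(h) for x in range(w)],
        )

    def test_radius_zero_is_identity(self):
        fm = self._fm(np.arange(12.0), 4, 3)
        out = pp.spatial_denoise(fm, radius=0)
        np.testing.assert_array_equal(out.values, fm.values)

    def test_salt_pixel_restored_by_median(self):
        values = np.full(9, 7.0)
        values[4] = 500.0  # centre pixel of the 3x3 grid
        out = pp.spatial_denoise(self._fm(values, 3, 3), radius=1)
        assert out.values[4, 0] == 7.0

    def test_constant_matrix_unchanged(self):
        fm = self._fm(np.full(25, 3.3), 5, 5)
        out = pp.spatial_denoise(fm, radius=2)
        np.testing.assert_array_equal(out.values, fm.values)

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            pp.spatial_denoise(self._fm(np.zeros(4), 2, 2), radius=-1)


class TestPickPeaks:
    def test_noise_free_single_peptide_cube(self):
        ds, _roi, _truth = synth.simulate_dataset(noise_free_single_peptide_config())
        peaks = pp.pick_peaks(ds)
        assert len(peaks) == 1
        assert abs(peaks[0] - 1505.83) <= 0.125  # within half the m/z step
        assert abs(peaks[0] - 1505.83) <= 0.01   # log-parabolic refinement

    def test_flat_zero_cube_yields_no_peaks(self):
        mz = 700.0 + 0.25 * np.arange(100)
        ds = md.MSIDataset.from_matrix([(0, 0), (1, 0)], mz, np.zeros((2, 100)))
        assert len(pp.pick_peaks(ds)) == 0

    def test_nonpositive_snr_rejected(self, small_sim):
        _cfg, ds, _roi, _truth = small_sim
        with pytest.raises(ParameterError):
            pp.pick_peaks(ds, snr_min=0.0)


class TestExtractFeatures:
    def test_noise_free_values_equal_planted_apex(self):
        cfg = noise_free_single_peptide_config()
        ds, roi, truth = synth.simulate_dataset(cfg)
        fm = pp.extract_features(ds, np.array([1505.83]), tol=0.5)
        labels = roi.labels_for(ds)
        pep = cfg.peptide_panel[0]
        want = truth.expected_apex(pep, f"{md.NIFTP}:{md.RAS_MUTANT}")
        np.testing.assert_allclose(fm.values[labels == md.NIFTP, 0], want)
        np.testing.assert_array_equal(fm.values[labels != md.NIFTP, 0], 0.0)

    def test_close_candidates_merged(self):
        ds, _roi, _truth = synth.simulate_dataset(noise_free_single_peptide_config())
        fm = pp.extract_features(ds, np.array([1505.80, 1505.90]), tol=0.5)
        assert fm.n_features == 1

    def test_default_cube_feature_count_is_panel_size(self, default_sim, feature_matrix):
        cfg, _ds, _roi, _truth = default_sim
        assert feature_matrix.n_features == len(cfg.peptide_panel)

    def test_csv_round_trip(self, tmp_path, small_sim):
        _cfg, ds, _roi, _truth = small_sim
        fm = pp.preprocess_dataset(ds, tophat_width=51)
        path = fm.to_csv(str(tmp_path / "features.csv"))
        back = pp.FeatureMatrix.from_csv(path)
        assert back.pixel_index == fm.pixel_index
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-6)


class TestEndToEndRecovery:
    def test_all_planted_peptides_recovered_within_one_sigma(
        self, default_sim, feature_matrix
    ):
        cfg, _ds, _roi, _truth = default_sim
        for pep in cfg.peptide_panel:
            err = np.min(np.abs(feature_matrix.feature_mz - pep.theoretical_mz))
            assert err <= pep.peak_sigma

    def test_extracted_region_means_track_planted_means(
        self, default_sim, feature_matrix
    ):
        """Pearson r >= 0.99 between mean extracted apex and planted apex,
        per region profile, across the 30-peptide panel."""
        cfg, _ds, _roi, truth = default_sim
        profiles = truth.pixel_profile.astype(str)
        order = [
            int(np.argmin(np.abs(feature_matrix.feature_mz - p.theoretical_mz)))
            for p in cfg.peptide_panel
        ]
        for key in np.unique(profiles):
            rows = profiles == key
            measured = feature_matrix.values[rows][:, order].mean(axis=0)
            planted = np.array([truth.expected_apex(p, key) for p in cfg.peptide_panel])
            r = np.corrcoef(measured, planted)[0, 1]
            assert r >= 0.99
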