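import math

import numpy as np
import pytest
import pywt

from meascreen.features import (FeatureDictionary, K_MARKERS,
                                QuiescentSignalError, build_feature_matrix,
                                calcium_biomarkers, fp_biomarkers,
                                ratio_to_control, repolarization_markers,
                                segment_fp, wavelet_features,
                                wavelet_positions)
from meascreen.signals import TimeSignal
from meascreen.tissue import WellConfig, grid_preset, simulate_well_pair
from meascreen.compounds import reference_compound_table


class TestSegmentation:
    def test_windows_bracket_spike_and_wave(self, fp_template):
        depol, plateau, repol = segment_fp(fp_template())
        assert depol.start <= 100.0 <= depol.end
        assert repol.start <= 400.0 <= repol.end
        assert depol.end <= plateau.start <= repol.end
        assert depol.start < depol.end

    def test_flat_trace_is_quiescent(self):
        with pytest.raises(QuiescentSignalError):
            segment_fp(TimeSignal(np.zeros(500), 1.0))

    def test_translation_equivariance(self, fp_template):
        a = segment_fp(fp_template(spike_t=100.0, wave_t=400.0))
        b = segment_fp(fp_template(spike_t=150.0, wave_t=450.0))
        for wa, wb in zip(a, b):
            assert wb.start == pytest.approx(wa.start + 50.0, abs=2.0)
            assert wb.end == pytest.approx(wa.end + 50.0, abs=2.0)


class TestFpBiomarkers:
    def test_depolarization_amplitude_max_minus_min(self, fp_template):
        b = fp_biomarkers(fp_template(spike_pos=200.0, spike_neg=100.0))
        assert b.da == pytest.approx(300.0, rel=0.01)

    def test_repolarization_center_and_duration(self, fp_template):
        b = fp_biomarkers(fp_template(spike_t=100.0, wave_t=400.0,
                                      wave_amp=40.0))
        assert b.rc == pytest.approx(400.0, abs=2.0)
        assert b.fpd == pytest.approx(300.0, abs=3.0)
        assert b.ra == pytest.approx(40.0, rel=0.02)

    def test_gaussian_halfwidth(self, fp_template):
        s = 20.0
        b = fp_biomarkers(fp_template(wave_sigma=s))
        assert b.rw == pytest.approx(2 * s * math.sqrt(2 * math.log(2)),
                                     abs=2.0)

    def test_baseline_shift_invariance(self, fp_template):
        b0 = fp_biomarkers(fp_template(offset=0.0))
        b1 = fp_biomarkers(fp_template(offset=50.0))
        for key, v0 in b0.as_dict().items():
            assert getattr(b1, key) == pytest.approx(v0, rel=0.02, abs=1.0)

    def test_wave_sign_invariance_of_ra(self, fp_template):
        up = fp_biomarkers(fp_template(wave_amp=40.0))
        down = fp_biomarkers(fp_template(wave_amp=-40.0))
        assert down.ra == pytest.approx(up.ra, rel=0.05)
        assert down.rc == pytest.approx(up.rc, abs=2.0)


class TestCalciumBiomarkers:
    def _transient(self, baseline=0.1, peak=0.6, dt=1.0):
        t = np.arange(0.0, 900.0, dt)
        v = np.full_like(t, baseline)
        tri = (t >= 200) & (t <= 600)
        v[tri] = baseline + (peak - baseline) * (
            1 - np.abs(t[tri] - 400.0) / 200.0)
        return TimeSignal(v, dt, 0.0, "uM")

    def test_amplitude(self):
        b = calcium_biomarkers(self._transient())
        assert b.ca == pytest.approx(0.5, rel=0.01)

    def test_cd50_of_symmetric_triangle_is_half_duration(self):
        b = calcium_biomarkers(self._transient(), x_percent=50.0)
        assert b.cdx == pytest.approx(200.0, abs=3.0)  # T/2 of T=400

    def test_decay_time(self):
        b = calcium_biomarkers(self._transient())
        # 90% recovery of the falling ramp: 0.9 * 200 ms after the peak
        assert b.dc == pytest.approx(180.0, abs=3.0)

    def test_flat_trace_rejected(self):
        with pytest.raises(QuiescentSignalError):
            calcium_biomarkers(TimeSignal(np.full(500, 0.1), 1.0))


class TestRatioToControl:
    def test_identical_records_give_unit_ratios(self):
        rec = {"da": 300.0, "fpd": 250.0}
        assert ratio_to_control(rec, rec) == {"da": 1.0, "fpd": 1.0}

    def test_direct_division(self):
        out = ratio_to_control({"da": 150.0}, {"da": 300.0})
        assert out["da"] == pytest.approx(0.5)

    def test_zero_control_flagged_not_infinite(self):
        out = ratio_to_control({"fpd": 100.0}, {"fpd": 0.0})
        assert math.isnan(out["fpd"])


class TestRepolarizationMarkers:
    def test_identical_windows_vanish(self):
        w = np.sin(np.linspace(0, 3, 64))
        km = repolarization_markers(w, w, n_points=None)
        assert (km.k1, km.k2, km.k3, km.k4) == (0.0, 0.0, 0.0, 0.0)

    def test_direct_formula_example(self):
        km = repolarization_markers(np.array([1.0, -1.0, 2.0]),
                                    np.zeros(3), n_points=None, dt=1.0)
        assert km.k1 == pytest.approx(4.0)
        assert km.k2 == pytest.approx(math.sqrt(6.0))
        assert km.k3 == pytest.approx(2.0 / 3.0)
        assert km.k4 == pytest.approx(2.0)
        assert km.k5 == pytest.approx(2.0)   # third sample at dt=1

    def test_constant_offset_closed_form(self):
        n, a = 64, 1.7
        c = np.random.default_rng(0).normal(size=n)
        km = repolarization_markers(c + a, c, n_points=None)
        assert km.k3 == pytest.approx(a)
        assert km.k4 == pytest.approx(a)
        assert km.k1 == pytest.approx(a ** 2)
        assert km.k2 == pytest.approx(a * math.sqrt(n))

    def test_sum_of_squares_dominates_max_term(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(size=32)
            c = rng.normal(size=32)
            km = repolarization_markers(d, c, n_points=None)
            assert km.k2 ** 2 >= km.k1 - 1e-12

    def test_resampling_of_unequal_windows(self):
        drug = TimeSignal(np.linspace(0, 1, 100), 1.0)
        ctrl = TimeSignal(np.linspace(0, 1, 80), 1.25)
        km = repolarization_markers(drug, ctrl, n_points=64)
        assert abs(km.k4) < 1e-9   # same shape after resampling

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            repolarization_markers(np.zeros(5), np.zeros(6), n_points=None)


class TestWavelets:
    def test_zero_windows_select_nothing(self):
        pos = wavelet_positions([np.zeros(64)], thr=0.1)
        assert pos.size == 0

    def test_constructed_sparse_positions_recovered(self):
        """Build windows by inverse transform of sparse coefficients."""
        w = pywt.Wavelet("db4")
        lev = pywt.dwt_max_level(64, w.dec_len)
        base = pywt.wavedec(np.zeros(64), w, mode="periodization", level=lev)
        arr, slices = pywt.coeffs_to_array(base)

        def window_from(positions, value=3.0):
            a = arr.copy()
            a[list(positions)] = value
            coeffs = pywt.array_to_coeffs(a, slices, output_format="wavedec")
            return pywt.waverec(coeffs, w, mode="periodization")

        w1 = window_from({3, 17})
        w2 = window_from({4, 17})
        assert set(wavelet_positions([w1], thr=1.0)) == {3, 17}
        assert set(wavelet_positions([w1, w2], thr=1.0)) == {3, 4, 17}

    def test_zero_window_zero_coefficients(self):
        res = wavelet_features(np.zeros(64), np.array([3, 17]))
        assert np.all(res.values == 0.0)
        assert not res.needs_refresh

    def test_reconstruction_within_tolerance_on_dictionary_windows(self):
        w = pywt.Wavelet("db4")
        lev = pywt.dwt_max_level(64, w.dec_len)
        base = pywt.wavedec(np.zeros(64), w, mode="periodization", level=lev)
        arr, slices = pywt.coeffs_to_array(base)
        arr[[3, 17]] = 2.0
        win = pywt.waverec(pywt.array_to_coeffs(arr, slices, "wavedec"), w,
                           mode="periodization")
        res = wavelet_features(win, np.array([3, 17]), l2_tolerance=1e-8)
        assert res.l2_error < 1e-8
        assert not res.needs_refresh

    def test_energy_outside_positions_triggers_refresh(self):
        w = pywt.Wavelet("db4")
        lev = pywt.dwt_max_level(64, w.dec_len)
        base = pywt.wavedec(np.zeros(64), w, mode="periodization", level=lev)
        arr, slices = pywt.coeffs_to_array(base)
        arr[[3, 25]] = 2.0
        win = pywt.waverec(pywt.array_to_coeffs(arr, slices, "wavedec"), w,
                           mode="periodization")
        res = wavelet_features(win, np.array([3]), thr=1.0, l2_tolerance=0.1)
        assert res.needs_refresh
        assert 25 in res.extra_positions

    def test_full_roundtrip_to_numerical_precision(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=64)
        res = wavelet_features(x, np.arange(64), l2_tolerance=np.inf)
        assert res.l2_error < 1e-10

    def test_bad_position_rejected(self):
        with pytest.raises(ValueError):
            wavelet_features(np.zeros(64), np.array([999]))

    def test_empty_training_list_rejected(self):
        with pytest.raises(ValueError):
            wavelet_positions([], thr=0.1)


@pytest.fixture(scope="module")
def surrogate_pairs():
    """Six paired surrogate wells for three reference compounds."""
    grid = grid_preset("96w8e", nx=15)
    cfg = WellConfig(backend="surrogate")
    table = {c.name: c for c in reference_compound_table()}
    pairs = []
    for seed, (name, dose) in enumerate([("Ibutilide", 0.018),
                                         ("Mexiletine", 38.0),
                                         ("Diltiazem", 0.76)] * 2):
        pairs.append(simulate_well_pair(table[name], dose, grid,
                                        seed=100 + seed, config=cfg))
    return pairs


class TestFeatureMatrix:
    def test_shape_and_column_names(self, surrogate_pairs):
        d = FeatureDictionary(use_wavelets=False)
        fm = build_feature_matrix(surrogate_pairs, d)
        assert fm.values.shape == (6, 7 + 3 + 5)
        assert list(fm.values.columns[:2]) == ["da_ratio", "fpd_ratio"]
        assert set(fm.tags.values()) == {"informed"}

    def test_identical_phases_give_unit_ratios_and_zero_k(self):
        grid = grid_preset("96w8e", nx=15)
        cfg = WellConfig(backend="surrogate", fp_noise_sd=0.0,
                         ca_noise_sd=0.0)
        table = {c.name: c for c in reference_compound_table()}
        ctrl, drug = simulate_well_pair(table["Ibutilide"], 0.0, grid,
                                        seed=3, config=cfg)
        d = FeatureDictionary(use_wavelets=False)
        fm = build_feature_matrix([(ctrl, drug)], d)
        row = fm.values.iloc[0]
        for m in ("da_ratio", "fpd_ratio", "ra_ratio", "ca_ratio"):
            assert row[m] == pytest.approx(1.0, abs=1e-6)
        for m in K_MARKERS[:4]:
            assert row[m] == pytest.approx(0.0, abs=1e-6)

    def test_row_order_follows_input_order(self, surrogate_pairs):
        d = FeatureDictionary(use_wavelets=False)
        fm = build_feature_matrix(surrogate_pairs, d)
        assert list(fm.provenance["sample_id"]) == list(range(6))
        assert fm.provenance["compound"].tolist() == [
            "Ibutilide", "Mexiletine", "Diltiazem"] * 2

    def test_wavelet_entries_learned_from_training(self, surrogate_pairs):
        d = FeatureDictionary(wavelet_threshold=20.0)
        d.fit_wavelets(surrogate_pairs)
        assert d.wavelet_positions_ is not None
        fm = build_feature_matrix(surrogate_pairs, d)
        wv_cols = [c for c in fm.values.columns if c.startswith("wv_")]
        assert len(wv_cols) == d.wavelet_positions_.size
        assert all(fm.tags[c] == "agnostic" for c in wv_cols)

    def test_imputation_uses_training_rows_only(self):
        # direct unit check of the imputation rule on a crafted matrix
        from types import SimpleNamespace
        rows = [{"a": 1.0, "b": np.nan}, {"a": 3.0, "b": 2.0},
                {"a": 5.0, "b": np.nan}]

        class _FakeDict:
            def entry_names(self):
                return ["a", "b"]

            def entry_tags(self):
                return {"a": "informed", "b": "informed"}

            def sample_features(self, ctrl, drug):
                return rows[ctrl.idx]

        pairs = [(SimpleNamespace(idx=i, well_id=f"w{i}", compound="X",
                                  concentration=1.0, seed=i),) * 2
                 for i in range(3)]
        fm = build_feature_matrix(pairs, _FakeDict(),
                                  train_mask=np.array([True, True, False]))
        # the only non-NaN training value of column b is 2.0
        assert fm.values["b"].tolist() == [2.0, 2.0, 2.0]

    def test_dictionary_definition_round_trip(self, surrogate_pairs,
                                              tmp_path):
        d = FeatureDictionary(wavelet_threshold=20.0, x_percent=80.0)
        d.fit_wavelets(surrogate_pairs)
        d.to_file(tmp_path / "dict.json")
        back = FeatureDictionary.from_file(tmp_path / "dict.json")
        assert back.entry_names() == d.entry_names()
        assert back.entry_tags() == d.entry_tags()
        assert back.x_percent == 80.0
        np.testing.assert_array_equal(back.wavelet_positions_,
                                      d.wavelet_positions_)

    def test_roundtrip_to_files(self, surrogate_pairs, tmp_path):
        d = FeatureDictionary(use_wavelets=False)
        fm = build_feature_matrix(surrogate_pairs, d)
        fm.to_files(tmp_path / "fm")
        from meascreen.features import FeatureMatrix
        back = FeatureMatrix.from_files(tmp_path / "fm")
        np.testing.assert_allclose(back.values.to_numpy(),
                                   fm.values.to_numpy(), rtol=1e-9)
        assert back.tags == fm.tags
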