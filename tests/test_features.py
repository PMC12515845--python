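import numpy as np
import pytest

from neurotriage import (
    SampEnParams,
    VMDConfig,
    extract_feature_table,
    extract_feature_table_from_recordings,
    feature_columns,
    generate_recording,
    psd_feature,
    read_feature_table,
    rms_feature,
    sample_entropy,
    segment_cohort,
    write_feature_table,
)

from .oracles import sampen_naive

FS = 250.0


class TestSampleEntropy:
    def test_constant_series_scores_zero(self):
        assert sample_entropy(np.full(50, 3.7), r_absolute=0.2) == 0.0
        assert sample_entropy(np.full(10, -1.0)) == 0.0  # sd = 0 path

    def test_huge_tolerance_scores_zero(self, rng):
        x = rng.uniform(size=60)
        assert sample_entropy(x, r_absolute=1e6) == 0.0

    def test_matches_naive_double_loop(self, rng):
        params = SampEnParams(m=2, r_factor=0.2)
        x = rng.uniform(size=100)
        r = params.r_factor * x.std()
        assert sample_entropy(x, params) == pytest.approx(
            sampen_naive(x, 2, r), abs=1e-12)

    def test_oracle_equivalence_over_many_series(self, rng):
        worst = 0.0
        for i in range(100):
            n = int(rng.integers(30, 301))
            x = rng.standard_normal(n)
            m = int(rng.integers(1, 4))
            r = 0.2 * x.std()
            got = sample_entropy(x, SampEnParams(m=m, r_factor=0.2))
            ref = sampen_naive(x, m, r)
            worst = max(worst, abs(got - ref))
        assert worst < 1e-10

    def test_entropy_decreases_with_tolerance(self, rng):
        x = rng.uniform(size=150)
        tight = sample_entropy(x, SampEnParams(m=2, r_factor=0.1))
        loose = sample_entropy(x, SampEnParams(m=2, r_factor=0.3))
        assert tight >= loose

    @pytest.mark.parametrize("a", [2.0, 0.5, 8.0, 3.7])
    def test_scale_invariance_with_relative_tolerance(self, a, rng):
        x = rng.standard_normal(120)
        assert sample_entropy(a * x) == sample_entropy(x)

    def test_degenerate_counts_use_documented_sentinel(self):
        x = 10.0 ** np.arange(12)  # no template pair ever matches
        q, m = len(x), 2
        expected = np.log((q - m) * (q - m - 1))
        assert sample_entropy(x, r_absolute=1e-3) == pytest.approx(expected)
        assert np.isnan(sample_entropy(x, r_absolute=1e-3, degenerate="nan"))

    def test_white_noise_more_complex_than_noisy_tone(self):
        t = np.arange(250) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        noise_wins = 0
        for s in range(50):
            g = np.random.default_rng(s)
            white = g.standard_normal(250)
            noisy_tone = tone + 0.05 * g.standard_normal(250)
            noise_wins += sample_entropy(white) > sample_entropy(noisy_tone)
        assert noise_wins == 50

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.zeros(3), SampEnParams(m=2))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SampEnParams(m=0)
        with pytest.raises(ValueError):
            SampEnParams(r_factor=0.0)


class TestAblationFeatures:
    def test_rms_of_constant_is_magnitude(self):
        assert rms_feature(np.full(40, -2.0), 20) == pytest.approx(2.0)
        assert rms_feature(np.zeros(40), 20) == 0.0

    def test_rms_averages_sub_windows(self):
        x = np.concatenate([np.ones(20), 3 * np.ones(20)])
        assert rms_feature(x, 20) == pytest.approx(2.0)

    def test_rms_sub_window_longer_than_series(self):
        with pytest.raises(ValueError):
            rms_feature(np.zeros(10), 20)

    def test_psd_of_zero_is_zero(self):
        assert psd_feature(np.zeros(40), FS, 20) == 0.0

    def test_psd_of_unit_tone_is_half(self):
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * 10 * t)
        assert psd_feature(x, FS, 250) == pytest.approx(0.5, rel=0.10)

    def test_psd_of_constant_concentrates_at_dc(self):
        from scipy.signal import periodogram
        x = np.full(20, 2.0)
        freqs, power = periodogram(x, fs=FS, window="boxcar", detrend=False)
        assert np.argmax(power) == 0
        assert psd_feature(x, FS, 20) > 0


@pytest.fixture(scope="module")
def windows(small_cohort):
    return segment_cohort(small_cohort[:2] + small_cohort[-2:], 1.0, 1.0)


class TestExtractFeatureTable:
    def test_default_configuration_yields_12_columns(self, windows):
        table = extract_feature_table(windows, VMDConfig(K=5), n_keep=4)
        assert len(feature_columns(table)) == 12
        assert len(table) == len(windows)
        assert table.columns[3] == "Fp1/IMF1/sampen"

    def test_column_count_scales_with_kinds_and_modes(self, windows):
        t = extract_feature_table(windows, VMDConfig(K=5), n_keep=4,
                                  feature_kinds=("sampen", "rms"))
        assert len(feature_columns(t)) == 24

    def test_rows_keep_acquisition_order(self, windows):
        table = extract_feature_table(windows, VMDConfig(K=3), n_keep=2)
        assert list(table["order_index"]) == list(range(len(table)))
        assert list(table["subject_id"]) == list(windows.subject_ids)

    def test_extraction_is_deterministic(self, windows):
        a = extract_feature_table(windows, VMDConfig(K=3), n_keep=2)
        b = extract_feature_table(windows, VMDConfig(K=3), n_keep=2)
        np.testing.assert_array_equal(a[feature_columns(a)].to_numpy(),
                                      b[feature_columns(b)].to_numpy())

    def test_batching_does_not_change_results(self, windows):
        a = extract_feature_table(windows, VMDConfig(K=3), n_keep=2,
                                  batch_size=7)
        b = extract_feature_table(windows, VMDConfig(K=3), n_keep=2,
                                  batch_size=512)
        np.testing.assert_array_equal(a[feature_columns(a)].to_numpy(),
                                      b[feature_columns(b)].to_numpy())

    def test_invalid_arguments(self, windows):
        with pytest.raises(ValueError):
            extract_feature_table(windows, VMDConfig(K=5), n_keep=9)
        with pytest.raises(ValueError):
            extract_feature_table(windows, VMDConfig(K=5), n_keep=4,
                                  feature_kinds=("wavelet",))


class TestRecordingScopeExtraction:
    def test_matches_window_scope_layout(self, small_cohort):
        recs = small_cohort[:2]
        table = extract_feature_table_from_recordings(
            recs, vmd_cfg=VMDConfig(K=5), n_keep=4)
        assert len(feature_columns(table)) == 12
        assert len(table) == 2 * 8  # 8-s recordings, 1-s windows
        assert list(table["order_index"]) == list(range(len(table)))

    def test_deterministic(self, small_cohort):
        recs = small_cohort[:1]
        a = extract_feature_table_from_recordings(recs, vmd_cfg=VMDConfig(K=3),
                                                  n_keep=2)
        b = extract_feature_table_from_recordings(recs, vmd_cfg=VMDConfig(K=3),
                                                  n_keep=2)
        np.testing.assert_array_equal(a[feature_columns(a)].to_numpy(),
                                      b[feature_columns(b)].to_numpy())

    def test_roundtrip_through_csv(self, small_cohort, tmp_path):
        table = extract_feature_table_from_recordings(
            small_cohort[:1], vmd_cfg=VMDConfig(K=3), n_keep=2)
        path = tmp_path / "features.csv"
        write_feature_table(table, path, config={"K": 3})
        back = read_feature_table(path)
        np.testing.assert_allclose(back[feature_columns(back)].to_numpy(),
                                   table[feature_columns(table)].to_numpy())
        assert (tmp_path / "features.csv.json").exists()
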