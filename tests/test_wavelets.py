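"""Meyer DWT/CWT features: band map, energies, entropies, transformer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from thermocomplexity.wavelets import (
    CWTMap,
    WaveletDecomposition,
    WaveletFeatureExtractor,
    cwt_band_features,
    cwt_map,
    dwt_decompose,
    scale_frequency_bands,
    wavelet_energy,
    wavelet_entropy,
)

# Published scale -> band map for fs = 0.1 Hz:
# (scale, f_min_hz, f_max_hz, period_min_min, period_max_min); the deepest
# scale's lower edge is printed only as "< 0.0001".
BAND_MAP_01HZ = [
    (1, 0.025, 0.05, 0.333333, 0.666667),
    (2, 0.0125, 0.025, 0.666667, 1.333333),
    (3, 0.00625, 0.0125, 1.333333, 2.666667),
    (4, 0.003125, 0.00625, 2.666667, 5.333333),
    (5, 0.001563, 0.003125, 5.333333, 10.666667),
    (6, 0.000781, 0.001563, 10.666667, 21.333333),
    (7, 0.000391, 0.000781, 21.333333, 42.666667),
    (8, 0.000195, 0.000391, 42.666667, 85.333333),
    (9, None, 0.000195, 85.333333, 170.666667),
]


class TestScaleFrequencyBands:
    def test_published_band_map_reproduced_to_6_decimals(self):
        bands = scale_frequency_bands(0.1, 9)
        for band, (scale, fmin, fmax, pmin, pmax) in zip(bands, BAND_MAP_01HZ):
            assert band.scale == scale
            if fmin is None:
                assert band.f_min_hz < 0.0001
            else:
                assert round(band.f_min_hz, 6) == fmin
            assert round(band.f_max_hz, 6) == fmax
            assert round(band.period_min_min, 6) == pmin
            assert round(band.period_max_min, 6) == pmax

    def test_dyadic_halving_at_unit_rate(self):
        b1 = scale_frequency_bands(1.0, 3)[0]
        assert (b1.f_min_hz, b1.f_max_hz) == (0.25, 0.5)

    def test_bands_tile_without_overlap(self):
        bands = scale_frequency_bands(0.1, 9)
        for hi, lo in zip(bands, bands[1:]):
            assert hi.f_min_hz == lo.f_max_hz

    def test_physiological_tags(self):
        tags = [b.tag for b in scale_frequency_bands(0.1, 9)]
        assert tags[0] == "neurogenic"
        assert tags[1] == tags[2] == "metabolic"
        assert all(t == "ultradian" for t in tags[3:])


class TestDWT:
    def test_zero_signal_gives_zero_coefficients(self):
        d = dwt_decompose(np.zeros(2048), fs_hz=0.1)
        assert all(np.all(c == 0) for c in d.details)
        assert np.all(d.approx == 0)

    def test_full_length_recording_has_nine_scales(self, rng):
        d = dwt_decompose(rng.normal(size=8640), fs_hz=0.1)
        assert d.n_scales == 9

    def test_too_short_signal_raises_with_minimum_length(self):
        with pytest.raises(ValueError, match="1024"):
            dwt_decompose(np.zeros(512), fs_hz=0.1)

    def test_parseval_energy_conservation(self, rng):
        """The exact Meyer filter bank is orthonormal: coefficient energy
        equals signal energy to machine precision on dyadic lengths."""
        x = rng.normal(size=4096)
        d = dwt_decompose(x, fs_hz=0.1)
        total = sum((c**2).sum() for c in d.details) + (d.approx**2).sum()
        assert abs(total - (x**2).sum()) / (x**2).sum() < 1e-6

    def test_coefficient_counts_halve_per_level(self, rng):
        d = dwt_decompose(rng.normal(size=2048), fs_hz=0.1)
        lengths = [len(c) for c in d.details]
        assert lengths == [1024, 512, 256, 128, 64, 32, 16, 8, 4]

    def test_sinusoid_energy_lands_in_nominal_scale(self):
        # 0.03 Hz at fs = 0.1 -> scale 1 band [0.025, 0.05]
        t = np.arange(8192)
        x = np.sin(2 * np.pi * 0.3 * t)  # 0.03 Hz in samples of 0.1 Hz rate
        d = dwt_decompose(x, fs_hz=0.1)
        energies = [(c**2).sum() for c in d.details]
        assert energies[0] / sum(energies) > 0.95


class TestWaveletEnergy:
    def _decomp(self, coeffs):
        return WaveletDecomposition(details=[np.asarray(coeffs, float)],
                                    approx=np.zeros(1), fs_hz=0.1)

    def test_zero_coefficients(self):
        assert wavelet_energy(self._decomp([0, 0, 0]), 1) == 0.0

    def test_mean_square(self):
        assert wavelet_energy(self._decomp([3, 4]), 1) == pytest.approx(12.5)

    def test_quadratic_homogeneity(self, rng):
        x = rng.normal(size=2048)
        e1 = wavelet_energy(dwt_decompose(x, fs_hz=0.1), 3)
        e2 = wavelet_energy(dwt_decompose(2 * x, fs_hz=0.1), 3)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            wavelet_energy(self._decomp([1.0]), 2)


class TestWaveletEntropy:
    def _decomp(self, coeffs):
        return WaveletDecomposition(details=[np.asarray(coeffs, float)],
                                    approx=np.zeros(1), fs_hz=0.1)

    def test_single_nonzero_coefficient_is_zero_entropy(self):
        assert wavelet_entropy(self._decomp([0, 5, 0, 0]), 1) == 0.0

    def test_uniform_magnitudes_reach_log_L(self):
        for L in (4, 16, 100):
            ent = wavelet_entropy(self._decomp(np.ones(L)), 1)
            assert ent == pytest.approx(np.log(L), rel=1e-12)

    def test_hand_computed_three_coefficient_case(self):
        # p = (1/4, 1/4, 1/2) -> H = 1.5 ln 2
        ent = wavelet_entropy(self._decomp([1.0, 1.0, np.sqrt(2)]), 1)
        assert ent == pytest.approx(1.5 * np.log(2), rel=1e-12)

    def test_all_zero_scale_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert wavelet_entropy(self._decomp([0.0, 0.0]), 1) == 0.0

    def test_log_base_option(self):
        d = self._decomp(np.ones(8))
        assert wavelet_entropy(d, 1, log_base="base-2") == pytest.approx(3.0)
        assert wavelet_entropy(d, 1, normalized=True) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=64))
    def test_entropy_bounds_hold_for_arbitrary_coefficients(self, coeffs):
        coeffs = np.asarray(coeffs)
        d = self._decomp(coeffs)
        if (coeffs**2).sum() == 0:
            return
        ent = wavelet_entropy(d, 1)
        assert -1e-12 <= ent <= np.log(len(coeffs)) + 1e-12

    def test_scale_invariance(self, rng):
        """Entropy depends on the normalized distribution only."""
        x = rng.normal(size=2048)
        e1 = wavelet_entropy(dwt_decompose(x, fs_hz=0.1), 4)
        e2 = wavelet_entropy(dwt_decompose(3.7 * x, fs_hz=0.1), 4)
        assert e2 == pytest.approx(e1, rel=1e-10)


class TestCWT:
    def test_zero_signal_gives_zero_map(self):
        m = cwt_map(np.zeros(2048), fs_hz=0.1)
        assert np.allclose(m.coeffs, 0)

    def test_map_shape_and_frequency_order(self, rng):
        m = cwt_map(rng.normal(size=1500), n_freqs=32, fs_hz=0.1)
        assert m.coeffs.shape == (32, 1500)
        assert np.all(np.diff(m.pseudo_freqs_hz) < 0)

    def test_sinusoid_peak_row_matches_frequency(self):
        t = np.arange(8192) / 0.1
        x = np.sin(2 * np.pi * 0.01 * t)
        m = cwt_map(x, fs_hz=0.1)
        peak = m.pseudo_freqs_hz[np.argmax(np.mean(np.abs(m.coeffs), axis=1))]
        assert 1 / 1.2 < peak / 0.01 < 1.2

    def test_out_of_range_frequencies_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            cwt_map(np.zeros(1024), pseudo_freqs_hz=np.array([0.2]), fs_hz=0.1)


class TestCWTBandFeatures:
    def _map(self, coeffs, freqs):
        return CWTMap(coeffs=np.asarray(coeffs, float),
                      pseudo_freqs_hz=np.asarray(freqs, float), fs_hz=0.1)

    def test_zero_map_gives_zero_features(self):
        m = self._map(np.zeros((4, 10)), [0.04, 0.01, 0.003, 0.0005])
        feats = cwt_band_features(m)
        assert all(v == 0 for v in feats.values())

    def test_single_nonzero_cell_in_band_two(self):
        coeffs = np.zeros((4, 10))
        coeffs[1, 3] = 2.5  # row at 0.01 Hz -> metabolic band
        m = self._map(coeffs, [0.04, 0.01, 0.003, 0.0005])
        assert cwt_band_features(m)["CWTentro2"] == 0.0

    def test_uniform_band_reaches_log_cell_count(self):
        coeffs = np.zeros((4, 10))
        coeffs[2, :] = 1.0  # 10 uniform cells in band 3
        m = self._map(coeffs, [0.04, 0.01, 0.003, 0.0005])
        feats = cwt_band_features(m)
        assert feats["CWTentro3_raw"] == pytest.approx(np.log(10))
        assert feats["CWTentro3"] == pytest.approx(1.0)

    def test_empty_band_raises_naming_it(self):
        m = self._map(np.zeros((2, 5)), [0.04, 0.01])
        with pytest.raises(ValueError, match="band3"):
            cwt_band_features(m)

    def test_energy_is_mean_square_over_band(self):
        coeffs = np.zeros((4, 10))
        coeffs[0, :] = 2.0
        m = self._map(coeffs, [0.04, 0.01, 0.003, 0.0005])
        assert cwt_band_features(m)["CWTen1"] == pytest.approx(4.0)


class TestFeatureTableAssembly:
    def test_one_row_per_subject_and_variant(self, small_cohort, feature_table):
        assert len(feature_table) == 2 * len(small_cohort)

    def test_at_least_thirty_features_per_row(self, feature_table):
        from thermocomplexity.features import feature_columns
        assert len(feature_columns(feature_table)) >= 30

    def test_no_missing_values(self, feature_table):
        assert not feature_table.drop(columns=["sofa"]).isna().any().any()

    def test_unknown_variant_rejected(self, small_cohort):
        from thermocomplexity.features import extract_features
        with pytest.raises(ValueError, match="variant"):
            extract_features(small_cohort[0], variants=("bogus",))


class TestTransformer:
    def test_transform_shape_and_names(self, rng):
        X = rng.normal(size=(3, 1500))
        tr = WaveletFeatureExtractor(fs_hz=0.1)
        out = tr.fit(X).transform(X)
        assert len(out) == 3
        names = tr.get_feature_names_out()
        assert "WEn_s5" in names and "CWTentro4" in names

    def test_sklearn_clone_compatible(self):
        tr = WaveletFeatureExtractor(n_freqs=16)
        assert clone(tr).get_params()["n_freqs"] == 16
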