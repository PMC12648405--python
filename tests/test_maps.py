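"""Distance-frequency maps: z-scored power, percent change, band tests."""
import itertools

import numpy as np
import pytest

import bprr
from bprr.maps import DistanceFrequencyMap, band_summary_tests, percent_change_map, sqrt_zscore_map
from bprr.montage import bin_pairs_by_distance, enumerate_omnidirectional_pairs, apply_bipolar
from bprr.preprocess import AnnotationTable, lowpass_downsample, notch_line_noise, parse_baseline_windows
from bprr.spectral import SpectrumSet, multitaper_psd

from conftest import line_array


def spectra(power):
    return SpectrumSet(power, np.arange(2.0, 2.0 + power.shape[1]))


def binned_line_pairs(n=6, pitch=4.0):
    return bin_pairs_by_distance(enumerate_omnidirectional_pairs(line_array(n, pitch)))


class TestSqrtZscoreMap:
    def test_rows_are_zero_mean_unit_sd(self, rng):
        pairs = binned_line_pairs()
        m = sqrt_zscore_map(spectra(rng.uniform(1, 10, size=(len(pairs), 30))), pairs)
        occ = ~np.isnan(m.values[0])
        assert occ.sum() >= 2
        assert np.allclose(np.nanmean(m.values[:, occ], axis=1), 0, atol=1e-9)
        assert np.allclose(np.nanstd(m.values[:, occ], axis=1), 1, atol=1e-9)

    def test_two_bin_population_sd_convention(self):
        # bin means 1 and 3 -> z = -1, +1 (hand computation fixes ddof=0)
        pairs = bin_pairs_by_distance(enumerate_omnidirectional_pairs(line_array(2, 4.0)),
                                      2.0, (2.0, 10.0))
        extra = bin_pairs_by_distance(enumerate_omnidirectional_pairs(line_array(2, 8.0)),
                                      2.0, (2.0, 10.0))
        import pandas as pd
        both = bprr.BipolarPairSet(pd.concat([pairs.pairs, extra.pairs], ignore_index=True),
                                   bin_width_mm=2.0, distance_range_mm=(2.0, 10.0))
        m = sqrt_zscore_map(spectra(np.array([[1.0], [9.0]])), both)
        got = m.values[0][~np.isnan(m.values[0])]
        assert np.allclose(got, [-1.0, 1.0])

    def test_identical_bins_give_zero_row(self):
        pairs = binned_line_pairs()
        m = sqrt_zscore_map(spectra(np.full((len(pairs), 5), 4.0)), pairs)
        occ = ~np.isnan(m.values[0])
        assert np.allclose(m.values[:, occ], 0.0)

    def test_single_bin_rejected(self):
        pairs = bin_pairs_by_distance(enumerate_omnidirectional_pairs(line_array(2, 4.0)))
        with pytest.raises(ValueError):
            sqrt_zscore_map(spectra(np.ones((1, 5))), pairs)


class TestPercentChangeMap:
    def test_zero_bipolar_is_minus_100(self):
        pairs = binned_line_pairs()
        bip = spectra(np.zeros((len(pairs), 10)))
        ref = spectra(np.ones((6, 10)))
        m = percent_change_map(bip, ref, pairs, min_pairs=1)
        occ = ~np.isnan(m.values)
        assert np.allclose(m.values[occ], -100.0)

    def test_legacy_sign_flips(self):
        pairs = binned_line_pairs()
        bip = spectra(np.zeros((len(pairs), 10)))
        ref = spectra(np.ones((6, 10)))
        m = percent_change_map(bip, ref, pairs, min_pairs=1, legacy_sign=True)
        occ = ~np.isnan(m.values)
        assert np.allclose(m.values[occ], 100.0)

    def test_independent_noise_doubles_linear_power(self, rng):
        # Var(X - Y) = 2 sigma^2: percent change -> +100% on the linear scale
        n_win = 500
        x = rng.standard_normal((n_win, 2, 256))
        pairs = bin_pairs_by_distance(enumerate_omnidirectional_pairs(line_array(2, 30.0)))
        bip = multitaper_psd(apply_bipolar(x, pairs), 256.0, fmax=100)
        ref = multitaper_psd(x, 256.0, fmax=100)
        m = percent_change_map(bip, ref, pairs, scale="linear", min_pairs=1)
        vals = m.values[~np.isnan(m.values)]
        assert abs(vals.mean() - 100.0) < 5.0

    def test_plane_wave_at_lambda_over_6_is_zero(self):
        # oracle: 4 sin^2(pi/6) = 1 -> bipolar equals referential
        lam, d = 72.0, 12.0
        array = line_array(2, d)
        cfg = bprr.FieldConfig(waves=[bprr.WaveComponent(10.0, 1.0, speed_m_s=10 * lam / 1000)],
                               seed=3)
        rec = bprr.simulate_field(array, cfg, 20.0, fs=256.0)
        wins = rec.samples.reshape(2, -1, 256).transpose(1, 0, 2)
        pairs = bin_pairs_by_distance(enumerate_omnidirectional_pairs(array))
        bip = multitaper_psd(apply_bipolar(wins, pairs), 256.0, fmax=100)
        ref = multitaper_psd(wins, 256.0, fmax=100)
        m = percent_change_map(bip, ref, pairs, min_pairs=1)
        f10 = np.where(m.frequencies == 10.0)[0][0]
        val = m.values[f10][~np.isnan(m.values[f10])][0]
        assert abs(val) < 2.0

    def test_min_pairs_cells_are_na(self, rng):
        pairs = binned_line_pairs()
        bip = spectra(rng.uniform(1, 2, (len(pairs), 5)))
        ref = spectra(rng.uniform(1, 2, (6, 5)))
        m = percent_change_map(bip, ref, pairs, min_pairs=10)
        assert np.all(np.isnan(m.values))

    def test_frequency_grid_mismatch_rejected(self):
        pairs = binned_line_pairs()
        with pytest.raises(ValueError):
            percent_change_map(spectra(np.ones((len(pairs), 5))),
                               SpectrumSet(np.ones((6, 5)), np.arange(3.0, 8.0)), pairs)


def wilcoxon_exact_oracle(diffs):
    """Exhaustive two-sided signed-rank p over all sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    total = ranks.sum()
    stats = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([0, 1], repeat=n)]
    w_min = min(w_obs, total - w_obs)
    p = sum(1 for w in stats if min(w, total - w) <= w_min) / 2 ** n
    return min(p, 1.0)


class TestBandSummaryTests:
    def _subject_inputs(self, offsets):
        bip, ref = {}, {}
        freqs = np.arange(2.0, 201.0)
        for i, off in enumerate(offsets):
            base = np.full((3, 199), 10.0)
            bip[f"s{i}"] = {4.0: SpectrumSet(base + off, freqs)}
            ref[f"s{i}"] = SpectrumSet(base, freqs)
        return bip, ref

    def test_identical_inputs_no_rejections(self):
        bip, ref = self._subject_inputs([0.0] * 6)
        table = band_summary_tests(bip, ref)
        assert (table["effect_size"].fillna(0) == 0).all()
        assert not table["significant"].any()

    def test_wilcoxon_matches_exhaustive_oracle(self):
        diffs = [1.0, 2.0, 3.0, 4.0, 5.0, -1.0]
        from bprr.stats import paired_wilcoxon
        res = paired_wilcoxon(np.array(diffs), np.zeros(6))
        assert res["p"] == pytest.approx(wilcoxon_exact_oracle(diffs), abs=1e-9)

    def test_single_subject_suppresses_statistics(self):
        bip, ref = self._subject_inputs([1.0])
        table = band_summary_tests(bip, ref)
        assert table["p"].isna().all()
        assert not table["significant"].any()

    def test_reference_config_delta_attenuated_at_4mm(self):
        """Short-distance bipolar derivation attenuates delta-band power."""
        from bprr.montage import enumerate_linear_ordinal_pairs
        bip, ref = {}, {}
        for i, seed in enumerate((11, 12)):
            array = bprr.make_geometry("grid1x16")
            rec = bprr.simulate_field(array, bprr.reference_field_config(seed=seed),
                                      20.0, fs=512.0)
            rec = notch_line_noise(rec)
            w = parse_baseline_windows(rec, AnnotationTable.empty())
            ps = enumerate_linear_ordinal_pairs(array, max_skip=1)
            bip[f"s{i}"] = {4.0: multitaper_psd(apply_bipolar(w.data, ps), 512.0)}
            ref[f"s{i}"] = multitaper_psd(w.data, 512.0)
        table = band_summary_tests(bip, ref)
        delta = table[(table["band"] == "delta") & (table["distance_mm"] == 4.0)]
        assert delta["median_diff"].iloc[0] < 0


class TestDistanceFrequencyMapIO:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.normal(size=(5, 4))
        vals[:, 2] = np.nan
        m = DistanceFrequencyMap(vals, np.arange(2.0, 7.0), np.array([3., 5., 7., 9.]),
                                 np.array([2, 2, 0, 2]), "percent_change")
        m.to_tsv(tmp_path / "m.tsv")
        back = DistanceFrequencyMap.from_tsv(tmp_path / "m.tsv")
        assert np.allclose(back.values, m.values, equal_nan=True, atol=1e-9)

    def test_empty_bin_must_be_nan(self):
        with pytest.raises(ValueError):
            DistanceFrequencyMap(np.zeros((2, 2)), np.arange(2.0, 4.0),
                                 np.array([3.0, 5.0]), np.array([0, 1]), "x")
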