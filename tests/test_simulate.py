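"""Synthetic field generator and its closed-form oracles."""
import numpy as np
import pytest

import bprr
from bprr.montage import apply_bipolar, enumerate_omnidirectional_pairs
from bprr.simulate import (AperiodicField, CommonMode, FieldConfig, IedConfig,
                           WaveComponent, analytic_pair_power_ratio, inject_ieds,
                           inject_task_modulation, make_geometry, simulate_field)


class TestMakeGeometry:
    def test_grid16x16(self):
        a = make_geometry("grid16x16")
        assert a.n_contacts == 256
        d = np.linalg.norm(a.positions[None] - a.positions[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(4.0)
        assert set(a.table["row_id"]) == {f"row{i}" for i in range(16)}

    def test_depth10_span(self):
        a = make_geometry("depth10")
        assert a.n_contacts == 10
        span = np.linalg.norm(a.positions[-1] - a.positions[0])
        assert span == pytest.approx(45.0)  # 9 gaps x 5 mm

    def test_strip_kinds(self):
        assert make_geometry("strip4").n_contacts == 4
        assert make_geometry("strip6").table["pitch_mm"].iloc[0] == 10.0

    def test_jitter_determinism(self):
        a = make_geometry("grid1x8", jitter_mm=0.5, seed=9)
        b = make_geometry("grid1x8", jitter_mm=0.5, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_geometry("tripolar7")


class TestAnalyticPairPowerRatio:
    def test_zero_distance(self):
        assert analytic_pair_power_ratio(0.0, 48.0) == 0.0

    def test_half_wavelength_maximum(self):
        assert analytic_pair_power_ratio(24.0, 48.0, 0.0) == pytest.approx(4.0)

    def test_sixth_wavelength_reversal_point(self):
        assert analytic_pair_power_ratio(8.0, 48.0) == pytest.approx(1.0)

    def test_oblique_pair_uses_projected_distance(self):
        assert (analytic_pair_power_ratio(10.0, 60.0, np.pi / 3)
                == pytest.approx(analytic_pair_power_ratio(5.0, 60.0)))

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValueError):
            analytic_pair_power_ratio(4.0, 0.0)


class TestSimulateField:
    def test_common_mode_only_cancels_in_bipolar(self):
        a = make_geometry("grid1x4")
        cfg = FieldConfig(common_mode=CommonMode(), seed=5)
        rec = simulate_field(a, cfg, 4.0, fs=512.0)
        ps = enumerate_omnidirectional_pairs(a)
        bip = apply_bipolar(rec.samples, ps)
        assert np.allclose(bip, 0.0, atol=1e-9)

    def test_bit_reproducible(self):
        a = make_geometry("grid1x4")
        cfg = bprr.reference_field_config(seed=3)
        r1 = simulate_field(a, cfg, 3.0, fs=512.0)
        r2 = simulate_field(a, bprr.reference_field_config(seed=3), 3.0, fs=512.0)
        assert np.array_equal(r1.samples, r2.samples)

    def test_single_wave_ratio_matches_oracle_at_reversal(self):
        # lambda = 72 mm, colinear pair at d = 12 mm = lambda/6 -> ratio 1
        a = make_geometry("grid1x2", pitch_mm=12.0)
        cfg = FieldConfig(waves=[WaveComponent(10.0, 1.0, speed_m_s=0.72)], seed=2)
        rec = simulate_field(a, cfg, 60.0, fs=512.0)
        x = rec.samples
        ratio = (x[0] - x[1]).var() / (0.5 * (x[0].var() + x[1].var()))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_aperiodic_coherence_ratio(self):
        # d = l = 4 mm -> bipolar/referential power ratio 2(1 - 1/e) = 1.264
        a = make_geometry("grid1x2", pitch_mm=4.0)
        cfg = FieldConfig(aperiodic=AperiodicField(band_hz=(30, 200), std=1.0,
                                                   coherence_mm=4.0), seed=4)
        rec = simulate_field(a, cfg, 60.0, fs=512.0)
        x = rec.samples
        ratio = (x[0] - x[1]).var() / (0.5 * (x[0].var() + x[1].var()))
        assert ratio == pytest.approx(2 * (1 - np.exp(-1)), abs=0.08)

    def test_empirical_ratio_sweep_matches_oracle(self):
        """Bipolar/referential power ratio across d and lambda matches 4sin^2."""
        for lam in (40.0, 120.0):
            a = make_geometry("grid1x21", pitch_mm=2.0)
            f0 = 10.0
            cfg = FieldConfig(waves=[WaveComponent(f0, 1.0, speed_m_s=f0 * lam / 1000)],
                              seed=6)
            rec = simulate_field(a, cfg, 20.0, fs=512.0)
            x = rec.samples
            for d in (2, 8, 14, 20, 30, 40):
                emp = (x[0] - x[d // 2]).var() / (0.5 * (x[0].var() + x[d // 2].var()))
                ana = analytic_pair_power_ratio(d, lam)
                assert abs(emp - ana) <= 0.05 * max(ana, 1.0)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_field(make_geometry("grid1x2"), FieldConfig(), 1.0)


class TestInjectIeds:
    def test_annotation_count(self):
        a = make_geometry("grid1x8")
        rec = simulate_field(a, FieldConfig(aperiodic=AperiodicField(std=1.0)), 40.0,
                             fs=512.0)
        _, ann = inject_ieds(rec, a, IedConfig(n_events=20, center_contact=4, seed=1))
        assert (ann.table["kind"] == "ied").sum() == 20

    def test_gaussian_footprint_amplitude_ratio(self):
        a = make_geometry("grid1x5", pitch_mm=8.0)  # contacts at 0, 8, ..., 32 mm
        rec = bprr.Recording(np.zeros((5, 512 * 10)), 512.0, a.contact_ids)
        out, ann = inject_ieds(rec, a, IedConfig(n_events=3, center_contact=0,
                                                 sigma_mm=8.0, amplitude=100.0, seed=2))
        peak0 = np.abs(out.samples[0]).max()
        peak16 = np.abs(out.samples[2]).max()  # contact at 16 mm = 2 sigma
        assert peak16 / peak0 == pytest.approx(np.exp(-2), rel=1e-6)

    def test_zero_events_bitwise_unchanged(self):
        a = make_geometry("grid1x4")
        rec = simulate_field(a, FieldConfig(aperiodic=AperiodicField(std=1.0)), 5.0,
                             fs=512.0)
        out, ann = inject_ieds(rec, a, IedConfig(n_events=0))
        assert np.array_equal(out.samples, rec.samples)
        assert len(ann.table) == 0

    def test_events_separated_by_at_least_1s(self):
        a = make_geometry("grid1x4")
        rec = simulate_field(a, FieldConfig(aperiodic=AperiodicField(std=1.0)), 80.0,
                             fs=512.0)
        _, ann = inject_ieds(rec, a, IedConfig(n_events=30, seed=3))
        gaps = ann.table["onset_s"].to_numpy()[1:] - ann.table["offset_s"].to_numpy()[:-1]
        assert np.all(gaps >= 1.0 - 1e-9)

    def test_insufficient_duration_rejected(self):
        a = make_geometry("grid1x4")
        rec = simulate_field(a, FieldConfig(aperiodic=AperiodicField(std=1.0)), 5.0,
                             fs=512.0)
        with pytest.raises(ValueError):
            inject_ieds(rec, a, IedConfig(n_events=50))


class TestInjectTaskModulation:
    def _rec(self, seed=0, n_ch=2, dur=60.0):
        a = make_geometry(f"grid1x{n_ch}")
        cfg = FieldConfig(aperiodic=AperiodicField(band_hz=(2, 200), std=5.0), seed=seed)
        return a, simulate_field(a, cfg, dur, fs=512.0)

    @staticmethod
    def band_power(x, fs, lo, hi):
        from scipy import signal as sg
        f, p = sg.welch(x, fs, nperseg=512)
        return p[(f >= lo) & (f <= hi)].sum()

    def test_gain_one_is_identity(self):
        a, rec = self._rec()
        out, _ = inject_task_modulation(rec, ["G1"], [(10.0, 20.0)], gain=1.0)
        assert np.allclose(out.samples, rec.samples)

    def test_band_power_ratio_matches_gain(self):
        a, rec = self._rec(seed=8)
        out, _ = inject_task_modulation(rec, ["G1"], [(5.0, 55.0)],
                                        gain_band=(50.0, 200.0), gain=1.5, seed=1)
        fs = 512.0
        seg = slice(int(5 * fs), int(55 * fs))
        ratio = (self.band_power(out.samples[0, seg], fs, 50, 200)
                 / self.band_power(rec.samples[0, seg], fs, 50, 200))
        assert ratio == pytest.approx(1.5, rel=0.10)

    def test_non_subset_contacts_unmodulated(self):
        a, rec = self._rec(seed=9)
        out, _ = inject_task_modulation(rec, ["G1"], [(5.0, 55.0)],
                                        gain_band=(50.0, 200.0), gain=1.5, seed=1)
        fs = 512.0
        seg = slice(int(5 * fs), int(55 * fs))
        ratio = (self.band_power(out.samples[1, seg], fs, 50, 200)
                 / self.band_power(rec.samples[1, seg], fs, 50, 200))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_overlapping_intervals_merged(self):
        a, rec = self._rec()
        out, ann = inject_task_modulation(rec, ["G1"], [(5.0, 10.0), (8.0, 15.0)],
                                          gain=1.2, seed=2)
        assert len(ann.table) == 1
        assert ann.table["offset_s"].iloc[0] == 15.0
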