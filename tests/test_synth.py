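"""Generator contracts: schedule structure, injected-effect fidelity,
determinism, and the ARFI forward model."""

import numpy as np
import pytest
from dataclasses import replace

from tusvep import synth
from tusvep.arfi import EncodingParams
from tusvep.synth import (
    EvokedParams,
    GammaParams,
    SimConfig,
    evoked_template,
    gaussian_focus,
    make_event_table,
    simulate_arfi_pair,
    simulate_eeg,
)


class TestEventTable:
    def test_single_sonication_block_schedule(self, default_config):
        ev = make_event_table(default_config, ["LGN1"])
        # 20 sections x 3 stimulus conditions x 15 stimuli at 1 Hz
        assert len(ev) == 20 * 3 * 15
        assert (ev["condition"].value_counts() == 300).all()
        light_only = ev[ev["condition"] == "light"]
        assert len(light_only) == 300
        assert light_only["light_on"].all() and not light_only["tus_on"].any()

    def test_baseline_block_is_light_only(self, default_config):
        ev = make_event_table(default_config, ["Baseline"])
        assert len(ev) == 5 * 60  # 5 min at 1 Hz
        assert (ev["condition"] == "light").all()
        assert not ev["tus_on"].any()

    def test_onsets_strictly_increasing_and_1hz(self, default_config):
        ev = make_event_table(default_config, ["Baseline", "LGN1"])
        d = np.diff(ev["onset_s"].to_numpy())
        assert (d > 0).all()
        within = ev[ev["condition"] == "light"].groupby(
            ev["onset_s"].floordiv(60))["onset_s"].diff().dropna()
        assert np.allclose(within[within < 10], 1.0)

    def test_empty_and_unknown_blocks_error(self, default_config):
        with pytest.raises(ValueError):
            make_event_table(default_config, [])
        with pytest.raises(ValueError, match="unknown block"):
            make_event_table(default_config, ["NotABlock"])

    def test_scaled_down_block(self, default_config):
        ev = make_event_table(default_config, [("LGN1", 3)])
        assert len(ev) == 3 * 3 * 15


class TestSimulateEEG:
    def test_noiseless_single_event_reproduces_template(self, quiet_config):
        ev = make_event_table(quiet_config, [("Baseline", 1)]).iloc[:1]
        raw = simulate_eeg(ev, quiet_config, duration_s=5.0)
        occ = [i for i, c in enumerate(quiet_config.channels)
               if c.region == "occipital"]
        i0 = int(round(ev["onset_s"].iloc[0] * raw.fs))
        t_ms = np.arange(400)  # template support
        expected = evoked_template(t_ms, quiet_config.evoked)
        np.testing.assert_allclose(raw.data[occ[0], i0:i0 + 400], expected,
                                   atol=1e-12)

    def test_frontal_copy_is_attenuated(self, quiet_config):
        ev = make_event_table(quiet_config, [("Baseline", 1)]).iloc[:1]
        raw = simulate_eeg(ev, quiet_config, duration_s=5.0)
        i0 = int(round(ev["onset_s"].iloc[0] * raw.fs))
        fro = [i for i, c in enumerate(quiet_config.channels)
               if c.region == "frontal"][0]
        occ = [i for i, c in enumerate(quiet_config.channels)
               if c.region == "occipital"][0]
        ratio = raw.data[fro, i0:i0 + 400] / raw.data[occ, i0:i0 + 400]
        np.testing.assert_allclose(ratio[np.abs(raw.data[occ, i0:i0+400]) > 1],
                                   quiet_config.frontal_gain)

    def test_suppression_scales_evoked_exactly_without_noise(self, quiet_config):
        cfg = replace(quiet_config, suppression={"LGN1": 0.5})
        ev = make_event_table(cfg, [("Baseline", 1), ("LGN1", 1)])
        raw = simulate_eeg(ev, cfg)
        occ = [i for i, c in enumerate(cfg.channels)
               if c.region == "occipital"][0]
        base = ev[(ev["block"] == "Baseline")].iloc[0]
        lgn = ev[(ev["block"] == "LGN1") & (ev["condition"] == "light")].iloc[0]
        i_b = int(round(base["onset_s"] * raw.fs))
        i_l = int(round(lgn["onset_s"] * raw.fs))
        np.testing.assert_allclose(raw.data[occ, i_l:i_l + 400],
                                   0.5 * raw.data[occ, i_b:i_b + 400],
                                   atol=1e-12)

    def test_determinism_bit_identical(self, default_config):
        ev = make_event_table(default_config, [("LGN1", 1)])
        a = simulate_eeg(ev, default_config)
        b = simulate_eeg(ev, default_config)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ(self, default_config):
        ev = make_event_table(default_config, [("LGN1", 1)])
        a = simulate_eeg(ev, default_config)
        b = simulate_eeg(ev, replace(default_config, seed=default_config.seed + 1))
        assert not np.array_equal(a.data, b.data)

    def test_events_beyond_duration_error(self, default_config):
        ev = make_event_table(default_config, [("Baseline", 1)])
        with pytest.raises(ValueError, match="duration"):
            simulate_eeg(ev, default_config, duration_s=10.0)

    def test_random_phase_bursts_cancel_in_average(self):
        """Non-phase-locked bursts survive in single trials but average out
        of the evoked response — the structural premise of the NPL split."""
        cfg = SimConfig(
            seed=3, noise_scale_uv=0.0,
            evoked=EvokedParams(n70_amplitude_uv=0.0, p100_amplitude_uv=0.0),
            gamma_burst=GammaParams(amplitude_uv=5.0, latencies_ms=(90.0,)),
            tus_artifact=synth.TusArtifactParams(amplitude_uv=0.0),
        )
        ev = make_event_table(cfg, [("Baseline", 4)])  # 240 trials
        raw = simulate_eeg(ev, cfg)
        occ = [i for i, c in enumerate(cfg.channels) if c.region == "occipital"][0]
        onsets = (ev["onset_s"].to_numpy() * cfg.fs).round().astype(int)
        trials = np.stack([raw.data[occ, i:i + 400] for i in onsets])
        burst_win = slice(70, 110)
        single_rms = np.sqrt((trials[:, burst_win] ** 2).mean())
        avg_rms = np.sqrt((trials.mean(axis=0)[burst_win] ** 2).mean())
        assert single_rms > 1.0  # bursts present per trial
        assert avg_rms < single_rms / 5  # but nearly gone from the average

    def test_phantom_mode_artifact_confined_to_tus_window(self):
        cfg = synth.phantom_config(seed=9, noise_scale_uv=0.0)
        ev = make_event_table(cfg, [("LGN1", 1)])
        raw = simulate_eeg(ev, cfg)
        tus_ev = ev[ev["tus_on"]]
        onsets = (tus_ev["onset_s"].to_numpy() * cfg.fs).round().astype(int)
        inside = np.concatenate([raw.data[0, i:i + 300] for i in onsets])
        after = np.concatenate([raw.data[0, i + 320:i + 600] for i in onsets])
        assert np.abs(inside).max() > 0
        assert np.abs(after).max() == 0


class TestGaussianFocus:
    def test_peak_and_fwhm(self):
        f = gaussian_focus((41, 41, 41), 1.0, (20.0, 20.0, 20.0), 8.0, 2.5)
        assert f[20, 20, 20] == pytest.approx(2.5)
        assert f[24, 20, 20] == pytest.approx(1.25, rel=1e-9)  # FWHM/2 = 4 mm

    def test_integral_matches_gaussian_volume(self):
        fwhm, peak, d = 6.0, 1.0, 0.5
        f = gaussian_focus((81, 81, 81), d, (20.0, 20.0, 20.0), fwhm, peak)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        expected = peak * (sigma * np.sqrt(2 * np.pi)) ** 3 / d**3
        assert f.sum() == pytest.approx(expected, rel=1e-3)

    def test_center_outside_grid_errors(self):
        with pytest.raises(ValueError, match="outside"):
            gaussian_focus((11, 11), 1.0, (20.0, 5.0), 3.0, 1.0)


class TestSimulateARFIPair:
    def test_zero_field_zero_noise_identical_phases(self):
        enc = EncodingParams(tau_s=3e-3)
        p, m = simulate_arfi_pair(np.zeros((5, 5)), enc, 0.0, 0)
        np.testing.assert_array_equal(p, m)

    def test_phase_difference_peak_matches_forward_formula(self):
        enc = EncodingParams(tau_s=3e-3)
        field = gaussian_focus((21, 21), 1.0, (10.0, 10.0), 4.0, 1e-6)
        p, m = simulate_arfi_pair(field, enc, 0.0, 0)
        expected = 2 * enc.gamma_rad_per_s_per_T * enc.G_T_per_m * enc.tau_s * 1e-6
        assert (p - m).max() == pytest.approx(expected, rel=1e-12)

    def test_deterministic_given_seed(self):
        enc = EncodingParams(tau_s=3e-3)
        field = np.full((4, 4), 5e-7)
        a = simulate_arfi_pair(field, enc, 0.05, seed=11)
        b = simulate_arfi_pair(field, enc, 0.05, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_encoding_rejected(self):
        field = np.zeros((3, 3))
        with pytest.raises(ValueError):
            simulate_arfi_pair(field, EncodingParams(G_T_per_m=-1, tau_s=1e-3), 0, 0)
        with pytest.raises(ValueError):
            simulate_arfi_pair(field, EncodingParams(tau_s=None), 0, 0)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_arfi_pair(np.array([[-1e-6]]), EncodingParams(tau_s=1e-3), 0, 0)


class TestConfigValidation:
    def test_suppression_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="suppression"):
            SimConfig(suppression={"LGN1": 1.5})

    def test_evoked_latencies_must_fit_detection_windows(self):
        with pytest.raises(ValueError):
            EvokedParams(n70_latency_ms=50.0)
        with pytest.raises(ValueError):
            EvokedParams(p100_latency_ms=140.0)
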