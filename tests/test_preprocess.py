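"""Filtering, epoching, rejection, equalization and ICA cleaning."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochs
from tusvep.preprocess import (
    ComponentThresholds,
    bandpass,
    decompose_components,
    epoch,
    equalize_trials,
    reject_amplitude_artifacts,
    remove_components,
    score_and_flag_components,
)
from tusvep.synth import Channel, RawEEG

FS = 1000.0


def _raw(data):
    data = np.atleast_2d(data)
    channels = tuple(
        Channel(f"O{i+1}", "occipital", "left") for i in range(data.shape[0])
    )
    return RawEEG(data=data, fs=FS, channels=channels)


def _events(onsets_s, block="Baseline", condition="light"):
    return pd.DataFrame({
        "onset_s": onsets_s, "block": block, "condition": condition,
        "light_on": True, "tus_on": False,
    })


class TestBandpass:
    def test_dc_removed(self):
        raw = _raw(np.full((1, 5000), 7.0))
        out = bandpass(raw)
        mid = out.data[0, 1000:-1000]
        assert np.abs(mid).max() < 1e-6 * 7.0

    def test_passband_10hz_preserved(self):
        t = np.arange(10000) / FS
        raw = _raw(np.sin(2 * np.pi * 10 * t))
        out = bandpass(raw)
        mid = out.data[0, 2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_80hz_attenuated_20db(self):
        t = np.arange(10000) / FS
        raw = _raw(np.sin(2 * np.pi * 80 * t))
        out = bandpass(raw)
        mid = out.data[0, 2000:-2000]
        assert np.abs(mid).max() < 10 ** (-20 / 20)

    def test_invalid_band_rejected(self):
        raw = _raw(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            bandpass(raw, 50.0, 2.0)
        with pytest.raises(ValueError):
            bandpass(raw, 2.0, 600.0)


class TestEpoch:
    def test_index_arithmetic(self):
        data = np.arange(3000, dtype=float)[None, :]
        ep = epoch(_raw(data), _events([1.0]))
        assert ep.data.shape == (1, 1, 1000)
        # epoch covers samples 800..1799 inclusive
        assert ep.data[0, 0, 0] == 800.0
        assert ep.data[0, 0, -1] == 1799.0
        assert ep.time_ms[200] == 0.0

    def test_event_near_edge_skipped_with_warning(self):
        data = np.zeros((1, 3000))
        with pytest.warns(UserWarning, match="skipped"):
            ep = epoch(_raw(data), _events([0.05, 1.0]))
        assert ep.n_trials == 1

    def test_labels_preserved(self):
        data = np.zeros((2, 400000))
        onsets = np.arange(1, 300 + 1, dtype=float)
        ev = _events(onsets, block="LGN1", condition="light+tus")
        ep = epoch(_raw(data), ev)
        assert ep.n_trials == 300
        assert (ep.labels["block"] == "LGN1").all()
        assert (ep.labels["condition"] == "light+tus").all()


class TestAmplitudeRejection:
    def test_clean_epochs_not_rejected(self):
        ep = make_epochs(np.zeros((10, 2, 1000)))
        out = reject_amplitude_artifacts(ep, 100.0)
        assert out.accepted.all()

    def test_injected_deflections_flagged_exactly(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, size=(40, 3, 1000))
        bad = [3, 11, 17, 25, 39]
        data[bad, 1, 500] = 500.0
        out = reject_amplitude_artifacts(make_epochs(data), 100.0)
        assert sorted(np.where(~out.accepted)[0]) == bad

    def test_infinite_threshold_keeps_all(self):
        data = np.random.default_rng(1).normal(0, 50, size=(5, 2, 100))
        out = reject_amplitude_artifacts(make_epochs(data), np.inf)
        assert out.accepted.all()

    def test_data_never_mutated(self):
        data = np.random.default_rng(2).normal(0, 200, size=(5, 2, 100))
        ep = make_epochs(data)
        out = reject_amplitude_artifacts(ep, 100.0)
        assert np.array_equal(out.data, data)
        assert not out.accepted.all()


class TestEqualizeTrials:
    def test_keeps_chronologically_first(self):
        ep = make_epochs(np.zeros((300, 1, 100)))
        out = equalize_trials(ep, n=250)
        assert out.accepted.sum() == 250
        assert out.accepted[:250].all() and not out.accepted[250:].any()

    def test_exact_count_is_identity(self):
        ep = make_epochs(np.zeros((250, 1, 100)))
        out = equalize_trials(ep, n=250)
        assert out.accepted.all()

    def test_shortfall_warns_and_keeps_all(self):
        ep = make_epochs(np.zeros((200, 1, 100)))
        with pytest.warns(UserWarning, match="only 200"):
            out = equalize_trials(ep, n=250)
        assert out.accepted.all()

    def test_rejected_trials_not_counted(self):
        ep = make_epochs(np.zeros((60, 1, 100)))
        ep.accepted[:10] = False
        out = equalize_trials(ep, n=40)
        assert out.accepted.sum() == 40
        assert not out.accepted[:10].any()
        assert out.accepted[10:50].all()


def _mixture_epochs(seed=0, n_trials=40, n_time=1000):
    """Known 3-source mixture: an evoked component repeated every trial, a
    sustained 10 Hz oscillation, and a bursty 30 Hz artifact."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_time) / FS
    evoked = np.exp(-0.5 * ((t - 0.3) / 0.02) ** 2)
    sources = np.zeros((3, n_trials, n_time))
    for k in range(n_trials):
        sources[0, k] = evoked
        sources[1, k] = np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
        env = np.zeros(n_time)
        if k % 2 == 0:  # bursty: present only on half the trials
            env[400:700] = 1.0
        sources[2, k] = env * np.sin(2 * np.pi * 30 * t + rng.uniform(0, 2 * np.pi))
    mixing = np.array([
        [1.0, 0.8, 0.1],
        [0.6, -0.7, 0.12],
        [0.4, 0.3, 1.4],
        [-0.5, 0.9, 0.05],
    ])
    data = np.einsum("cs,skt->kct", mixing, sources)
    return make_epochs(data), sources, mixing


class TestICA:
    def test_two_channel_source_recovery(self):
        rng = np.random.default_rng(4)
        n = 20000
        s = np.stack([np.sign(np.sin(2 * np.pi * 7 * np.arange(n) / FS)),
                      rng.laplace(size=n)])
        mixing = np.array([[1.0, 0.5], [0.4, 1.2]])
        x = (mixing @ s).reshape(2, 20, 1000).transpose(1, 0, 2)
        ep = make_epochs(x)
        d = decompose_components(ep, seed=0)
        rec = d.sources
        corr = np.abs(np.corrcoef(np.vstack([s, rec]))[:2, 2:])
        # each true source matches some component almost perfectly
        assert corr.max(axis=1).min() > 0.95

    def test_reconstruct_identity_without_removal(self):
        ep, _, _ = _mixture_epochs()
        d = decompose_components(ep, seed=0)
        X = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
        err = np.abs(d.reconstruct() - X).max() / np.abs(X).max()
        assert err < 1e-6

    def test_single_channel_errors(self):
        ep = make_epochs(np.zeros((5, 1, 100)))
        with pytest.raises(ValueError, match="2 channels"):
            decompose_components(ep)

    def test_rank_deficient_names_channels(self):
        data = np.random.default_rng(0).normal(size=(10, 3, 500))
        data[:, 2] = data[:, 0]  # duplicate channel
        ep = make_epochs(data)
        with pytest.raises(ValueError, match="O3"):
            decompose_components(ep)

    def test_scoring_flags_artifact_only(self):
        ep, _, _ = _mixture_epochs()
        d = decompose_components(ep, seed=0)
        d = score_and_flag_components(d, ep)
        flagged = np.where(d.flags)[0]
        assert len(flagged) == 1
        # the flagged component is the bursty 30 Hz artifact: dominant
        # mixing weight on channel 3 and high band ratio
        k = flagged[0]
        assert d.scores.loc[k, "band_ratio"] > 0.5
        assert np.argmax(np.abs(d.mixing[:, k])) == 2

    def test_erp_component_protected(self):
        ep, _, _ = _mixture_epochs()
        d = decompose_components(ep, seed=0)
        d = score_and_flag_components(d, ep)
        erp_like = int(d.scores["erp_similarity"].idxmax())
        assert d.scores.loc[erp_like, "erp_similarity"] > 0.6  # above protection
        assert not d.flags[erp_like]

    def test_pure_30hz_component_flagged_by_band_ratio(self):
        t = np.arange(1000) / FS
        rng = np.random.default_rng(1)
        evoked = np.exp(-0.5 * ((t - 0.3) / 0.03) ** 2)
        data = np.zeros((40, 3, 1000))
        for k in range(40):
            # muscle-like: 30 Hz with a fresh phase per trial (not evoked)
            s30 = np.sin(2 * np.pi * 30 * t + rng.uniform(0, 2 * np.pi))
            noise = rng.normal(size=1000)
            data[k, 0] = evoked + 0.9 * s30 + 0.1 * noise
            data[k, 1] = 0.7 * evoked - 0.5 * s30 + 0.1 * noise
            data[k, 2] = 0.4 * evoked + 0.2 * s30 + rng.normal(size=1000)
        ep = make_epochs(data)
        d = decompose_components(ep, seed=0)
        d = score_and_flag_components(d, ep)
        k = int(d.scores["band_ratio"].idxmax())
        assert d.scores.loc[k, "band_ratio"] > 0.9
        assert d.flags[k]

    def test_remove_components_reduces_artifact_power(self):
        ep, sources, _ = _mixture_epochs()
        d = decompose_components(ep, seed=0)
        d = score_and_flag_components(d, ep)
        clean = remove_components(ep, d)
        # artifact window on the artifact-dominant channel
        before = (ep.data[::2, 2, 400:700] ** 2).mean()
        after = (clean.data[::2, 2, 400:700] ** 2).mean()
        assert after < before / 10

    def test_remove_nothing_is_identity(self):
        ep, _, _ = _mixture_epochs()
        d = decompose_components(ep, seed=0)
        d = score_and_flag_components(
            d, ep, ComponentThresholds(band_ratio=0.99, concentration=0.99,
                                       power_cv=100.0))
        assert not d.flags.any()
        clean = remove_components(ep, d)
        np.testing.assert_allclose(clean.data, ep.data, atol=1e-8)

    def test_all_flagged_refused(self):
        ep, _, _ = _mixture_epochs()
        d = decompose_components(ep, seed=0)
        d = score_and_flag_components(d, ep)
        d.flags[:] = True
        with pytest.raises(ValueError, match="all components"):
            remove_components(ep, d)
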