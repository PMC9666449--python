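"""Synthetic-data generator for TUS visual-evoked-potential experiments.

The generator emulates the statistical structure the analysis chain assumes:

* a block/condition schedule in which each sonication block is split into
  one-minute sections of four interleaved 15 s conditions (no-stim,
  light-only, TUS-only, light+TUS) with 1 Hz stimulus repetition, preceded by
  a 5 min light-only baseline block;
* evoked responses with an N70 trough and P100 peak on occipital electrodes
  (attenuated volume-conducted copy on frontal electrodes), multiplicatively
  suppressed by a per-block factor;
* 1/f (pink) background noise;
* stimulus-locked gamma bursts whose phase is drawn fresh per trial
  (non-phase-locked) or locked across trials;
* a broadband electromagnetic TUS artifact gated by the 300 ms pulse-train
  envelope, decaying with electrode–transducer distance;
* occasional large blink-like frontal deflections;
* Gaussian focal displacement fields encoded into MR-ARFI phase-image pairs.

Everything is driven by one seeded :class:`numpy.random.Generator` per call:
identical configuration (including seed) yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arfi import EncodingParams

__all__ = [
    "Channel",
    "EvokedParams",
    "GammaParams",
    "TusArtifactParams",
    "BlinkParams",
    "SimConfig",
    "RawEEG",
    "BLOCK_LABELS",
    "CONDITIONS",
    "default_channels",
    "phantom_config",
    "make_event_table",
    "evoked_template",
    "simulate_eeg",
    "gaussian_focus",
    "simulate_arfi_pair",
]

#: Block labels of the experimental timeline: a 5 min light-only baseline,
#: two sonication blocks on the visual-thalamus target, three on an
#: off-target control site.
BLOCK_LABELS = ("Baseline", "LGN1", "LGN2", "Ctrl1", "Ctrl2", "Ctrl3")

#: Conditions cycled within each one-minute section of a sonication block.
CONDITIONS = ("no-stim", "light", "tus", "light+tus")

_SECTION_S = 60.0
_CONDITION_S = 15.0
_STIM_RATE_HZ = 1.0
_BASELINE_SECTIONS = 5  # 5 min light-only baseline
_BLOCK_SECTIONS = 20  # 20 min sonication blocks
_TUS_TRAIN_S = 0.300  # pulse-train duration gating the EM artifact


@dataclass(frozen=True)
class Channel:
    """EEG electrode metadata.

    ``distance_cm`` is the electrode–transducer distance used by the
    electromagnetic-artifact model (the transducer sits over the vertex, so
    frontal electrodes are closer than occipital ones).
    """

    name: str
    region: str  # "frontal" | "occipital"
    side: str  # "left" | "right"
    distance_cm: float = 5.0

    def __post_init__(self) -> None:
        if self.region not in ("frontal", "occipital"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")


def default_channels() -> tuple[Channel, ...]:
    """Default 8-electrode montage: 3 frontal + 5 occipital electrodes."""
    return (
        Channel("F1", "frontal", "left", 3.0),
        Channel("F2", "frontal", "right", 3.0),
        Channel("Fz", "frontal", "left", 2.5),
        Channel("O1", "occipital", "left", 6.0),
        Channel("O2", "occipital", "right", 6.0),
        Channel("O3", "occipital", "left", 6.5),
        Channel("O4", "occipital", "right", 6.5),
        Channel("Oz", "occipital", "left", 7.0),
    )


@dataclass(frozen=True)
class EvokedParams:
    """Two-lobe evoked template: a negative trough followed by a positive peak.

    Defaults put the trough at 80 ms and the peak at 110 ms, inside the
    N70 (60–100 ms) and P100 (90–130 ms) detection windows.
    """

    n70_latency_ms: float = 80.0
    n70_amplitude_uv: float = -15.0
    p100_latency_ms: float = 110.0
    p100_amplitude_uv: float = 20.0
    width_ms: float = 12.0  # Gaussian SD of each lobe

    def __post_init__(self) -> None:
        if not 60.0 <= self.n70_latency_ms <= 100.0:
            raise ValueError("n70_latency_ms must lie in [60, 100] ms")
        if not 90.0 <= self.p100_latency_ms <= 130.0:
            raise ValueError("p100_latency_ms must lie in [90, 130] ms")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")


@dataclass(frozen=True)
class GammaParams:
    """Stimulus-locked gamma bursts (Gaussian envelopes at fixed latencies).

    ``phase_policy='random-per-trial'`` draws a fresh uniform carrier phase
    per trial, making the bursts non-phase-locked: they vanish from the
    trial-averaged evoked response but survive in single-trial spectra.
    ``'locked'`` reuses one phase for every trial.
    """

    center_freq_hz: float = 40.0
    latencies_ms: tuple[float, ...] = (90.0, 280.0)
    envelope_sd_ms: float = 20.0
    amplitude_uv: float = 5.0
    phase_policy: str = "random-per-trial"

    def __post_init__(self) -> None:
        if self.phase_policy not in ("random-per-trial", "locked"):
            raise ValueError(f"unknown phase policy {self.phase_policy!r}")
        if self.envelope_sd_ms <= 0:
            raise ValueError("envelope_sd_ms must be positive")


@dataclass(frozen=True)
class TusArtifactParams:
    """Electromagnetic transducer artifact: broadband noise gated by the
    300 ms pulse-train envelope, with amplitude decaying exponentially with
    electrode–transducer distance (``amp * exp(-decay_per_cm * d)``)."""

    amplitude_uv: float = 20.0
    decay_per_cm: float = 0.3


@dataclass(frozen=True)
class BlinkParams:
    """Large slow frontal deflections occurring at random trials."""

    rate_per_trial: float = 0.0
    amplitude_uv: float = 150.0
    width_ms: float = 120.0


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the EEG simulator.

    ``suppression`` maps a block label to a multiplicative factor in [0, 1]
    applied to the evoked amplitude during that block; a value may also be a
    ``{"left": f, "right": f}`` mapping for side-specific suppression
    (suppression applies to channels on the given side). Missing blocks
    default to 1 (no suppression).
    """

    seed: int = 0
    channels: tuple[Channel, ...] = field(default_factory=default_channels)
    fs: float = 1000.0
    evoked: EvokedParams = field(default_factory=EvokedParams)
    noise_scale_uv: float = 12.0
    gamma_burst: GammaParams = field(default_factory=GammaParams)
    suppression: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=dict
    )
    frontal_gain: float = 0.4  # volume-conducted evoked copy on frontal sites
    tus_artifact: TusArtifactParams = field(default_factory=TusArtifactParams)
    blink: BlinkParams = field(default_factory=BlinkParams)

    def __post_init__(self) -> None:
        if self.fs <= 2 * max(self.gamma_burst.center_freq_hz, 55.0):
            raise ValueError("fs must exceed twice the highest generated frequency")
        for block, s in self.suppression.items():
            vals = s.values() if isinstance(s, Mapping) else (s,)
            for v in vals:
                if not 0.0 <= float(v) <= 1.0:
                    raise ValueError(
                        f"suppression for block {block!r} must lie in [0, 1]"
                    )

    def suppression_factor(self, block: str, side: str) -> float:
        s = self.suppression.get(block, 1.0)
        if isinstance(s, Mapping):
            return float(s[side])
        return float(s)


def phantom_config(seed: int = 0, **overrides) -> SimConfig:
    """Configuration emulating the tofu-phantom artifact control: no evoked
    response, no gamma bursts, only the TUS electromagnetic artifact on top
    of the noise floor."""
    cfg = SimConfig(
        seed=seed,
        evoked=EvokedParams(n70_amplitude_uv=0.0, p100_amplitude_uv=0.0),
        gamma_burst=GammaParams(amplitude_uv=0.0),
        **overrides,
    )
    return cfg


@dataclass
class RawEEG:
    """Continuous multi-channel recording in microvolts.

    ``data`` is channels x samples; channel metadata rides along so that
    downstream stages can select by cortical region and side.
    """

    data: np.ndarray
    fs: float
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples")
        if not np.isfinite(self.data).all():
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]


# ---------------------------------------------------------------------------
# Event schedule
# ---------------------------------------------------------------------------

def _block_sections(block: str | tuple[str, int]) -> tuple[str, int]:
    """Resolve a block spec to ``(label, n_sections)``.

    Plain labels get the study durations (5 min baseline, 20 min otherwise);
    ``(label, n_sections)`` tuples allow scaled-down schedules.
    """
    if isinstance(block, tuple):
        label, n_sections = block
    else:
        label, n_sections = block, None
    if label not in BLOCK_LABELS:
        raise ValueError(
            f"unknown block label {label!r}; expected one of {BLOCK_LABELS}"
        )
    if n_sections is None:
        n_sections = _BASELINE_SECTIONS if label == "Baseline" else _BLOCK_SECTIONS
    return label, int(n_sections)


def make_event_table(
    config: SimConfig,
    blocks: Sequence[str | tuple[str, int]],
    gap_s: float = 0.0,
    start_s: float = 1.0,
) -> pd.DataFrame:
    """Build the per-stimulus event table for a sequence of blocks.

    Each sonication block is split into one-minute sections of four 15 s
    conditions (no-stim, light, tus, light+tus); each stimulus condition
    delivers 15 stimuli at 1 Hz. The baseline block is continuous 1 Hz
    light-only stimulation. Returns a DataFrame with columns
    ``onset_s, block, condition, light_on, tus_on``, onsets strictly
    increasing.
    """
    if len(blocks) == 0:
        raise ValueError("blocks must be non-empty")
    rows: list[tuple[float, str, str, bool, bool]] = []
    t0 = float(start_s)  # leading margin so the first stimulus has epoch history
    for block in blocks:
        label, n_sections = _block_sections(block)
        if label == "Baseline":
            n_events = int(n_sections * _SECTION_S * _STIM_RATE_HZ)
            for k in range(n_events):
                rows.append((t0 + k / _STIM_RATE_HZ, label, "light", True, False))
            t0 += n_sections * _SECTION_S
        else:
            for s in range(n_sections):
                sec0 = t0 + s * _SECTION_S
                for ci, cond in enumerate(CONDITIONS):
                    if cond == "no-stim":
                        continue
                    c0 = sec0 + ci * _CONDITION_S
                    light = "light" in cond
                    tus = "tus" in cond
                    for k in range(int(_CONDITION_S * _STIM_RATE_HZ)):
                        rows.append((c0 + k / _STIM_RATE_HZ, label, cond, light, tus))
            t0 += n_sections * _SECTION_S
        t0 += gap_s
    table = pd.DataFrame(
        rows, columns=["onset_s", "block", "condition", "light_on", "tus_on"]
    )
    if not table["onset_s"].is_monotonic_increasing:
        raise AssertionError("event onsets are not increasing")  # pragma: no cover
    return table


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def evoked_template(t_ms: np.ndarray, params: EvokedParams) -> np.ndarray:
    """Evoked waveform on a post-stimulus time axis (ms): the sum of a
    negative Gaussian lobe at the N70 latency and a positive lobe at the
    P100 latency."""
    t = np.asarray(t_ms, dtype=float)
    w = params.width_ms
    lobe = lambda lat, amp: amp * np.exp(-0.5 * ((t - lat) / w) ** 2)  # noqa: E731
    return lobe(params.n70_latency_ms, params.n70_amplitude_uv) + lobe(
        params.p100_latency_ms, params.p100_amplitude_uv
    )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                rms: float) -> np.ndarray:
    """1/f-power noise via spectral shaping of white noise, normalized to the
    requested RMS per channel."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    noise = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    cur = noise.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return noise * (rms / cur)


def _tus_pulse_envelope(n: int, fs: float) -> np.ndarray:
    """On/off envelope of one 300 ms pulse train: 1 ms pulses every 2 ms
    (500 Hz PRF, 50% duty) inside the train, zero outside."""
    t = np.arange(n) / fs
    in_train = t < _TUS_TRAIN_S
    # 50% duty square wave at 500 Hz within the train
    within = (np.floor(t * 500.0 * 2.0).astype(int) % 2) == 0
    return (in_train & within).astype(float)


def simulate_eeg(
    events: pd.DataFrame,
    config: SimConfig,
    duration_s: float | None = None,
    pad_s: float = 1.0,
) -> RawEEG:
    """Synthesize a continuous EEG recording realizing an event table.

    Signal model per channel: pink-noise floor + (light events) evoked
    template scaled by the block/side suppression factor (full amplitude on
    occipital channels, ``frontal_gain`` on frontal) + non-phase-locked gamma
    bursts on occipital channels + (TUS events) pulse-train-gated broadband
    artifact on all channels + occasional frontal blink deflections.

    Deterministic given ``config.seed``.
    """
    fs = config.fs
    rng = np.random.default_rng(config.seed)
    if duration_s is None:
        duration_s = float(events["onset_s"].max()) + pad_s + 1.0
    n = int(round(duration_s * fs))
    if events["onset_s"].max() >= duration_s:
        raise ValueError("events exceed the simulated duration")

    n_ch = len(config.channels)
    data = _pink_noise(rng, n_ch, n, config.noise_scale_uv)

    occ = np.array([c.region == "occipital" for c in config.channels])
    frontal = ~occ

    # per-channel evoked gain: region gain x block/side suppression (per event)
    tmpl_t = np.arange(0, int(0.400 * fs)) / fs * 1e3  # 0..400 ms support
    base_tmpl = evoked_template(tmpl_t, config.evoked)
    burst = config.gamma_burst
    burst_len = int(0.400 * fs)
    burst_t = np.arange(burst_len) / fs * 1e3
    locked_phases = rng.uniform(0, 2 * np.pi, size=len(burst.latencies_ms))

    tus_len = int(round(_TUS_TRAIN_S * fs)) + 1
    tus_env = _tus_pulse_envelope(tus_len, fs)
    ch_artifact_gain = np.array(
        [
            config.tus_artifact.amplitude_uv
            * np.exp(-config.tus_artifact.decay_per_cm * c.distance_cm)
            for c in config.channels
        ]
    )

    blink_len = int(round(4 * config.blink.width_ms / 1e3 * fs))
    blink_t = (np.arange(blink_len) - blink_len / 2) / fs * 1e3
    blink_shape = np.exp(-0.5 * (blink_t / config.blink.width_ms) ** 2)

    for row in events.itertuples(index=False):
        i0 = int(round(row.onset_s * fs))
        if row.light_on:
            seg = slice(i0, i0 + len(base_tmpl))
            if seg.stop <= n:
                gains = np.where(occ, 1.0, config.frontal_gain) * np.array(
                    [
                        config.suppression_factor(row.block, c.side)
                        for c in config.channels
                    ]
                )
                data[:, seg] += gains[:, None] * base_tmpl[None, :]
                # gamma bursts on occipital channels
                if burst.amplitude_uv != 0:
                    for bi, lat in enumerate(burst.latencies_ms):
                        if burst.phase_policy == "random-per-trial":
                            phase = rng.uniform(0, 2 * np.pi)
                        else:
                            phase = locked_phases[bi]
                        env = np.exp(
                            -0.5 * ((burst_t - lat) / burst.envelope_sd_ms) ** 2
                        )
                        carrier = np.cos(
                            2 * np.pi * burst.center_freq_hz * burst_t / 1e3 + phase
                        )
                        wave = burst.amplitude_uv * env * carrier
                        data[occ, i0 : i0 + burst_len] += wave[None, :]
        if row.tus_on and ch_artifact_gain.any():
            seg = slice(i0, i0 + tus_len)
            if seg.stop <= n:
                carrier = rng.standard_normal(tus_len)
                data[:, seg] += ch_artifact_gain[:, None] * (tus_env * carrier)[None, :]
        if config.blink.rate_per_trial > 0 and rng.random() < config.blink.rate_per_trial:
            j0 = i0 + int(rng.integers(0, int(0.3 * fs)))
            seg = slice(j0, j0 + blink_len)
            if seg.stop <= n:
                data[frontal, seg] += config.blink.amplitude_uv * blink_shape[None, :]

    return RawEEG(data=data, fs=fs, channels=config.channels)


# ---------------------------------------------------------------------------
# MR-ARFI synthesis
# ---------------------------------------------------------------------------

def gaussian_focus(
    shape: tuple[int, ...],
    spacing_mm: tuple[float, ...] | float,
    center_mm: tuple[float, ...],
    fwhm_mm: float,
    peak: float,
) -> np.ndarray:
    """Isotropic Gaussian focal spot on a regular grid.

    ``center_mm`` is in physical coordinates with the origin at voxel
    ``(0, ..., 0)``. Used both as a displacement field (peak in meters or µm)
    and as a volumetric heat source (peak in W/m³).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * len(shape)
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != len(shape) or len(center_mm) != len(shape):
        raise ValueError("shape, spacing and center dimensionality must agree")
    for c, n, d in zip(center_mm, shape, spacing):
        if not 0.0 <= c <= (n - 1) * d:
            raise ValueError("center lies outside the grid")
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    axes = [np.arange(n) * d - c for n, d, c in zip(shape, spacing, center_mm)]
    r2 = np.zeros(shape)
    for k, ax in enumerate(axes):
        sl = [None] * len(shape)
        sl[k] = slice(None)
        r2 = r2 + (ax[tuple(sl)]) ** 2
    return peak * np.exp(-0.5 * r2 / sigma**2)


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phi))


def simulate_arfi_pair(
    field_m: np.ndarray,
    encoding: EncodingParams,
    noise_sd_rad: float = 0.0,
    seed: int = 0,
    base_phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a displacement field (meters) into a pair of phase images with
    opposite motion-encoding-gradient polarity.

    The phase difference of the returned ``(phase_plus, phase_minus)`` pair
    equals ``2 γ G τ · D`` plus zero-mean Gaussian noise of SD
    ``sqrt(2) * noise_sd_rad`` (each image carries independent noise of SD
    ``noise_sd_rad``). Deterministic given ``seed``.
    """
    field = np.asarray(field_m, dtype=float)
    if (field < 0).any():
        raise ValueError("displacement field must be non-negative")
    encoding.validate()
    rng = np.random.default_rng(seed)
    half = encoding.gamma_rad_per_s_per_T * encoding.G_T_per_m * encoding.tau_s * field
    noise_p = rng.normal(0.0, noise_sd_rad, size=field.shape) if noise_sd_rad else 0.0
    noise_m = rng.normal(0.0, noise_sd_rad, size=field.shape) if noise_sd_rad else 0.0
    phase_plus = _wrap_phase(base_phase + half + noise_p)
    phase_minus = _wrap_phase(base_phase - half + noise_m)
    return phase_plus, phase_minus


def with_suppression(config: SimConfig, suppression: Mapping[str, float | Mapping[str, float]]) -> SimConfig:
    """Return a copy of ``config`` with the given per-block suppression map."""
    return replace(config, suppression=dict(suppression))
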