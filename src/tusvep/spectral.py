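"""Morlet-wavelet time–frequency decomposition of epoched EEG.

Power is split into

* **total** power — per-trial wavelet decomposition, squared magnitude,
  averaged over trials;
* **non-phase-locked (NPL)** power — the same decomposition after the
  trial-averaged evoked response is subtracted from every trial, so only
  activity whose phase varies across trials survives;
* **phase-locked (PL)** power — total − NPL, elementwise.

Because the wavelet transform is linear, NPL ≤ total holds analytically and
PL is the power of the trial-averaged response; any negative PL values are
pure floating-point residue and are clipped before dB conversion.

Spectrograms are expressed as dB change relative to the −150..0 ms
pre-stimulus baseline: ``10·log10(power / per-frequency baseline mean)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sp_fft

from .preprocess import EpochedEEG

__all__ = [
    "WaveletFamily",
    "Spectrogram",
    "build_wavelets",
    "wavelet_transform",
    "single_trial_power",
    "total_power",
    "npl_power",
    "pl_power",
    "db_baseline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WaveletFamily:
    """Complex Morlet wavelets: center frequencies with per-frequency cycle
    counts, unit-energy normalized.

    The temporal SD of the Gaussian envelope is ``cycles / (2π f)``; more
    cycles at higher frequencies trade temporal precision for frequency
    precision.
    """

    freqs_hz: np.ndarray
    cycles: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, float)
        c = np.asarray(self.cycles, float)
        if f.ndim != 1 or len(f) < 2 or (np.diff(f) <= 0).any():
            raise ValueError("frequencies must be a strictly increasing vector")
        if len(c) != len(f):
            raise ValueError("cycles and frequencies must have equal length")
        if f[-1] >= self.fs / 2:
            raise ValueError("max frequency must lie below Nyquist")

    @property
    def n_freqs(self) -> int:
        return len(self.freqs_hz)

    def sigma_t(self) -> np.ndarray:
        """Temporal SD (s) of each wavelet's Gaussian envelope."""
        return self.cycles / (2.0 * np.pi * self.freqs_hz)

    def half_support(self) -> int:
        """Samples covering ±4 temporal SD of the widest wavelet."""
        return int(np.ceil(4.0 * self.sigma_t().max() * self.fs))

    def sample(self, i: int) -> np.ndarray:
        """Discretized wavelet ``i`` on a symmetric time grid (unit energy)."""
        st = self.sigma_t()[i]
        half = int(np.ceil(4.0 * st * self.fs))
        t = np.arange(-half, half + 1) / self.fs
        gauss = np.exp(-(t**2) / (2.0 * st**2))
        norm = (st * np.sqrt(np.pi)) ** -0.5
        return norm * gauss * np.exp(2j * np.pi * self.freqs_hz[i] * t)


def build_wavelets(
    fs: float,
    f_range: tuple[float, float] = (2.0, 55.0),
    n_freqs: int = 50,
    cycle_range: tuple[float, float] = (3.0, 10.0),
    spacing: str = "linear",
) -> WaveletFamily:
    """Construct the wavelet family: ``n_freqs`` center frequencies spanning
    ``f_range`` with cycle counts increasing linearly from ``cycle_range[0]``
    at the lowest frequency to ``cycle_range[1]`` at the highest.

    ``spacing`` selects linear (default) or logarithmic frequency spacing.
    """
    if n_freqs < 2:
        raise ValueError("n_freqs must be at least 2")
    if not 0 < f_range[0] < f_range[1] < fs / 2:
        raise ValueError("invalid frequency range")
    if spacing == "linear":
        freqs = np.linspace(f_range[0], f_range[1], n_freqs)
    elif spacing == "log":
        freqs = np.geomspace(f_range[0], f_range[1], n_freqs)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    cycles = np.linspace(cycle_range[0], cycle_range[1], n_freqs)
    return WaveletFamily(freqs_hz=freqs, cycles=cycles, fs=fs)


@dataclass
class Spectrogram:
    """Frequency x time power map.

    ``kind`` tags the decomposition branch (total | npl | pl), ``units`` is
    ``"raw"`` (µV²-scale) or ``"dB"`` after baselining.
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    time_ms: np.ndarray
    kind: str
    units: str = "raw"
    baseline_window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs_hz), len(self.time_ms)):
            raise ValueError("power must be freqs x time")


def _wavelet_ffts(family: WaveletFamily, n_fft: int) -> np.ndarray:
    """FFTs of all wavelets, centered for 'same'-style convolution output."""
    out = np.empty((family.n_freqs, n_fft), dtype=complex)
    for i in range(family.n_freqs):
        w = family.sample(i)
        half = (len(w) - 1) // 2
        kern = np.zeros(n_fft, dtype=complex)
        kern[: half + 1] = w[half:]
        kern[-half:] = w[:half]
        out[i] = sp_fft.fft(kern)
    return out


def wavelet_transform(data: np.ndarray, family: WaveletFamily) -> np.ndarray:
    """Complex wavelet coefficients of ``data`` (..., n_time) on the input
    time axis: shape (..., n_freqs, n_time).

    Edges are handled by reflection-padding each trace by one wavelet
    half-support before the frequency-domain convolution; the pad is cropped
    from the result.
    """
    data = np.asarray(data, dtype=float)
    n_time = data.shape[-1]
    pad = family.half_support()
    padded = np.concatenate(
        [data[..., 1 : pad + 1][..., ::-1], data, data[..., -pad - 1 : -1][..., ::-1]],
        axis=-1,
    )
    n_fft = sp_fft.next_fast_len(padded.shape[-1])
    wf = _wavelet_ffts(family, n_fft)
    df = sp_fft.fft(padded, n=n_fft, axis=-1)
    prod = df[..., None, :] * wf  # (..., n_freqs, n_fft)
    coef = sp_fft.ifft(prod, axis=-1)
    return coef[..., pad : pad + n_time]


def _select_trials(epochs: EpochedEEG, block, condition, channel_indices):
    trials = epochs.accepted_data(block, condition)
    if channel_indices is None:
        channel_indices = np.arange(epochs.n_channels)
    return trials[:, channel_indices, :]


def single_trial_power(trials: np.ndarray, family: WaveletFamily,
                       chunk: int = 16) -> np.ndarray:
    """Per-trial power stack: (n_trials, n_freqs, n_time).

    ``trials`` is (n_trials, n_time) — single channel or channel-averaged
    traces. Processed in chunks to bound memory.
    """
    trials = np.asarray(trials, dtype=float)
    n = trials.shape[0]
    out = None
    for i0 in range(0, n, chunk):
        coef = wavelet_transform(trials[i0 : i0 + chunk], family)
        p = (coef.real**2 + coef.imag**2)
        if out is None:
            out = np.empty((n,) + p.shape[1:], dtype=float)
        out[i0 : i0 + chunk] = p
    return out


def _mean_power(trials_cht: np.ndarray, family: WaveletFamily,
                chunk: int = 8) -> np.ndarray:
    """Trial- and channel-averaged power of (n_trials, n_ch, n_time) data."""
    n_trials = trials_cht.shape[0]
    acc = None
    for i0 in range(0, n_trials, chunk):
        coef = wavelet_transform(trials_cht[i0 : i0 + chunk], family)
        p = (coef.real**2 + coef.imag**2).sum(axis=0).mean(axis=0)
        acc = p if acc is None else acc + p
    return acc / n_trials


def total_power(epochs: EpochedEEG, family: WaveletFamily,
                block: str | None = None, condition: str | None = None,
                channel_indices: np.ndarray | None = None) -> Spectrogram:
    """Total power: per-trial decomposition, squared magnitude, averaged over
    trials (then over the selected channels)."""
    trials = _select_trials(epochs, block, condition, channel_indices)
    if trials.shape[0] == 0:
        raise ValueError("no accepted trials in the requested cell")
    return Spectrogram(
        power=_mean_power(trials, family), freqs_hz=family.freqs_hz,
        time_ms=epochs.time_ms, kind="total",
    )


def npl_power(epochs: EpochedEEG, family: WaveletFamily,
              block: str | None = None, condition: str | None = None,
              channel_indices: np.ndarray | None = None) -> Spectrogram:
    """Non-phase-locked power: the per-channel evoked response (mean over the
    same trials) is subtracted from each trial before decomposition, removing
    everything phase-consistent across trials."""
    trials = _select_trials(epochs, block, condition, channel_indices)
    if trials.shape[0] < 2:
        raise ValueError("NPL power requires at least 2 trials")
    residual = trials - trials.mean(axis=0, keepdims=True)
    return Spectrogram(
        power=_mean_power(residual, family), freqs_hz=family.freqs_hz,
        time_ms=epochs.time_ms, kind="npl",
    )


def pl_power(total: Spectrogram, npl: Spectrogram) -> Spectrogram:
    """Phase-locked power: ``total − NPL``, elementwise and exact."""
    if total.power.shape != npl.power.shape or not np.array_equal(
        total.freqs_hz, npl.freqs_hz
    ) or not np.array_equal(total.time_ms, npl.time_ms):
        raise ValueError("total and NPL spectrograms have mismatched axes")
    if total.units != "raw" or npl.units != "raw":
        raise ValueError("PL subtraction is defined on raw power")
    return Spectrogram(
        power=total.power - npl.power, freqs_hz=total.freqs_hz,
        time_ms=total.time_ms, kind="pl",
    )


def db_baseline(spec: Spectrogram,
                window_ms: tuple[float, float] = (-150.0, 0.0)) -> Spectrogram:
    """Convert raw power to dB change relative to the pre-stimulus baseline:
    ``10·log10(power / per-frequency mean over the window)``.

    Microscopically negative raw values (floating-point residue of the PL
    subtraction) are clipped to 0 first; the clip count is logged.
    """
    if spec.units != "raw":
        raise ValueError("spectrogram is already baselined")
    mask = (spec.time_ms >= window_ms[0]) & (spec.time_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("baseline window lies outside the time axis")
    power = spec.power
    n_neg = int((power < 0).sum())
    if n_neg:
        logger.info("clipped %d negative power value(s) before dB conversion", n_neg)
        power = np.clip(power, 0.0, None)
    base = power[:, mask].mean(axis=1, keepdims=True)
    if (base <= 0).any():
        raise ValueError("baseline power must be positive at every frequency")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power / base)
    return replace(spec, power=db, units="dB", baseline_window_ms=window_ms)
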