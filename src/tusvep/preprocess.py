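"""EEG pre-processing: filtering, epoching, artifact rejection, trial
equalization and ICA-based component cleaning.

The processing order is fixed: band-pass filter the continuous record,
section it into 1 s epochs (−200..+800 ms around stimulus onset), flag trials
with large deflections, equalize trial counts across condition cells, and —
for TUS-containing conditions only — decompose with ICA and remove components
matching the muscle/ultrasound-artifact criteria while protecting any
component whose time course resembles the evoked response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA

from .synth import Channel, RawEEG

__all__ = [
    "EpochedEEG",
    "ComponentDecomposition",
    "ComponentThresholds",
    "bandpass",
    "epoch",
    "reject_amplitude_artifacts",
    "equalize_trials",
    "decompose_components",
    "score_and_flag_components",
    "remove_components",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochedEEG:
    """Trials x channels x time array with per-trial labels and a rejection
    mask.

    ``accepted`` is True for trials that survive every rejection stage so
    far; rejection never mutates the voltage data, only this mask. The time
    axis is milliseconds relative to stimulus onset, closed-open
    [−pre, post).
    """

    data: np.ndarray  # (n_trials, n_channels, n_time), µV
    fs: float
    time_ms: np.ndarray
    labels: pd.DataFrame  # columns onset_s, block, condition, light_on, tus_on
    channels: tuple[Channel, ...]
    accepted: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.accepted is None:
            self.accepted = np.ones(self.n_trials, dtype=bool)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if len(self.labels) != self.n_trials or len(self.accepted) != self.n_trials:
            raise ValueError("labels/mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def cell_mask(self, block: str | None = None, condition: str | None = None
                  ) -> np.ndarray:
        m = np.ones(self.n_trials, dtype=bool)
        if block is not None:
            m &= (self.labels["block"] == block).to_numpy()
        if condition is not None:
            m &= (self.labels["condition"] == condition).to_numpy()
        return m

    def select(self, mask: np.ndarray) -> "EpochedEEG":
        """Subset trials (boolean or index mask); labels re-indexed."""
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels.iloc[mask].reset_index(drop=True),
            accepted=self.accepted[mask],
        )

    def accepted_data(self, block: str | None = None,
                      condition: str | None = None) -> np.ndarray:
        """Voltage array of accepted trials in a condition cell."""
        return self.data[self.accepted & self.cell_mask(block, condition)]

    def channel_indices(self, region: str | None = None,
                        side: str | None = None) -> np.ndarray:
        idx = [
            i
            for i, c in enumerate(self.channels)
            if (region is None or c.region == region)
            and (side is None or c.side == side)
        ]
        return np.asarray(idx, dtype=int)


def bandpass(raw: RawEEG, low_hz: float = 2.0, high_hz: float = 50.0,
             order: int = 4) -> RawEEG:
    """Zero-phase Butterworth band-pass (forward–backward), per channel.

    Zero-phase filtering preserves evoked-component latencies, which the
    N70/P100 windows depend on.
    """
    if not 0.0 < low_hz < high_hz < raw.fs / 2.0:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs={raw.fs} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=raw.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.data, axis=1)
    return RawEEG(data=filtered, fs=raw.fs, channels=raw.channels)


def epoch(raw: RawEEG, events: pd.DataFrame, pre_ms: float = 200.0,
          post_ms: float = 800.0) -> EpochedEEG:
    """Section the continuous record into per-stimulus epochs.

    Each epoch spans [−pre_ms, post_ms) around the event onset; at 1000 Hz
    with the defaults that is 1000 samples with t=0 at the onset sample.
    Events too close to a record edge are skipped with a warning rather than
    failing the whole run.
    """
    n_pre = int(round(pre_ms * raw.fs / 1e3))
    n_post = int(round(post_ms * raw.fs / 1e3))
    kept_rows = []
    segments = []
    skipped = 0
    for i, row in enumerate(events.itertuples(index=False)):
        i0 = int(round(row.onset_s * raw.fs))
        if i0 - n_pre < 0 or i0 + n_post > raw.n_samples:
            skipped += 1
            logger.warning("event %d at %.3f s too close to record edge; skipped",
                           i, row.onset_s)
            continue
        segments.append(raw.data[:, i0 - n_pre : i0 + n_post])
        kept_rows.append(i)
    if skipped:
        warnings.warn(f"{skipped} event(s) skipped (insufficient pre/post data)",
                      stacklevel=2)
    if not segments:
        raise ValueError("no events could be epoched")
    data = np.stack(segments, axis=0)
    time_ms = (np.arange(-n_pre, n_post) / raw.fs) * 1e3
    labels = events.iloc[kept_rows].reset_index(drop=True)
    return EpochedEEG(data=data, fs=raw.fs, time_ms=time_ms, labels=labels,
                      channels=raw.channels)


def reject_amplitude_artifacts(epochs: EpochedEEG,
                               threshold_uv: float = 100.0) -> EpochedEEG:
    """Flag trials whose absolute voltage exceeds the threshold on any
    channel. Data are untouched; only the acceptance mask shrinks."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    ok = peak <= threshold_uv
    n_new = int((~ok & epochs.accepted).sum())
    if n_new:
        logger.info("amplitude rejection flagged %d trial(s)", n_new)
    return replace(epochs, accepted=epochs.accepted & ok)


def equalize_trials(epochs: EpochedEEG, n: int = 250) -> EpochedEEG:
    """Per block x condition cell, keep the chronologically first ``n``
    accepted trials; surplus accepted trials are flagged out. Cells with
    fewer than ``n`` accepted trials keep all of them (with a warning)."""
    accepted = epochs.accepted.copy()
    order = np.argsort(epochs.labels["onset_s"].to_numpy(), kind="stable")
    cells = epochs.labels[["block", "condition"]].drop_duplicates()
    for block, condition in cells.itertuples(index=False):
        cell = epochs.cell_mask(block, condition)
        chron = order[cell[order] & accepted[order]]
        if len(chron) < n:
            warnings.warn(
                f"cell ({block}, {condition}) has only {len(chron)} accepted "
                f"trials (< {n}); keeping all", stacklevel=2)
            continue
        accepted[chron[n:]] = False
    return replace(epochs, accepted=accepted)


# ---------------------------------------------------------------------------
# ICA component cleaning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentThresholds:
    """Automated surrogates for the supervised component-rejection criteria:
    (a) excess 20–40 Hz band-power ratio, (b) spatial concentration of the
    mixing weights (stands in for clustered scalp topography), (c) temporal
    fluctuation (coefficient of variation) of short-window band power; a
    component whose trial-averaged time course correlates with the grand
    evoked response above ``erp_protect`` is never rejected."""

    band_ratio: float = 0.5
    concentration: float = 0.8
    power_cv: float = 1.0
    erp_protect: float = 0.6

    def __post_init__(self) -> None:
        for name in ("band_ratio", "concentration", "erp_protect"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.power_cv <= 0:
            raise ValueError("power_cv must be positive")


@dataclass
class ComponentDecomposition:
    """ICA decomposition of concatenated accepted epochs.

    ``mixing @ sources + mean[:, None]`` reconstructs the concatenated data
    to numeric tolerance when no component is removed. ``scores`` is filled
    by :func:`score_and_flag_components`.
    """

    mixing: np.ndarray  # (n_channels, n_components)
    sources: np.ndarray  # (n_components, n_trials * n_time)
    mean: np.ndarray  # (n_channels,)
    trial_index: np.ndarray  # indices of the epochs the sources came from
    n_time: int
    scores: pd.DataFrame | None = None
    flags: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Channels x samples reconstruction using the kept components."""
        if keep is None:
            keep = np.ones(self.n_components, dtype=bool)
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


def _rank_deficient_channels(X: np.ndarray) -> list[int]:
    """Heuristically name channels responsible for rank deficiency: zero
    variance, or near-perfect correlation with an earlier channel."""
    bad = [int(i) for i in np.where(X.std(axis=1) < 1e-12)[0]]
    good = [i for i in range(X.shape[0]) if i not in bad]
    if len(good) > 1:
        corr = np.corrcoef(X[good])
        for a in range(len(good)):
            for b in range(a):
                if abs(corr[a, b]) > 1.0 - 1e-9:
                    bad.append(good[a])
                    break
    return sorted(set(bad))


def decompose_components(epochs: EpochedEEG, n_components: int | None = None,
                         seed: int = 0, max_iter: int = 1000) -> ComponentDecomposition:
    """Blind source separation of the accepted epochs by FastICA.

    Epochs are concatenated along time; the decomposition is deterministic
    given ``seed``. Intended for TUS-containing conditions — the evoked
    analysis of light-only trials runs without component cleaning.
    """
    if epochs.n_channels < 2:
        raise ValueError("ICA requires at least 2 channels")
    idx = np.where(epochs.accepted)[0]
    if len(idx) == 0:
        raise ValueError("no accepted trials to decompose")
    X = epochs.data[idx].transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    bad = _rank_deficient_channels(X)
    if bad:
        names = [epochs.channels[i].name for i in bad]
        raise ValueError(f"rank-deficient data; offending channels: {names}")
    mean = X.mean(axis=1)
    # fewer independent sources than electrodes is normal; follow the
    # numerical rank unless the caller fixes the component count
    rank = int(np.linalg.matrix_rank(X @ X.T))
    k = n_components or min(epochs.n_channels, rank)
    ica = FastICA(n_components=k, whiten="unit-variance", random_state=seed,
                  max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on hard mixtures
        sources = ica.fit_transform((X - mean[:, None]).T).T
    return ComponentDecomposition(
        mixing=ica.mixing_, sources=sources, mean=mean, trial_index=idx,
        n_time=epochs.data.shape[2],
    )


def _band_power_ratio(source: np.ndarray, fs: float) -> float:
    f, p = signal.welch(source, fs=fs, nperseg=min(len(source), 1024))
    band = p[(f >= 20) & (f <= 40)].sum()
    total = p[(f >= 2) & (f <= 50)].sum()
    return float(band / total) if total > 0 else 0.0


def _power_cv(source: np.ndarray, fs: float, window_s: float = 1.0) -> float:
    w = int(window_s * fs)
    n_win = len(source) // w
    if n_win < 2:
        return 0.0
    p = (source[: n_win * w].reshape(n_win, w) ** 2).mean(axis=1)
    return float(p.std() / p.mean()) if p.mean() > 0 else 0.0


def score_and_flag_components(
    decomp: ComponentDecomposition,
    epochs: EpochedEEG,
    thresholds: ComponentThresholds = ComponentThresholds(),
) -> ComponentDecomposition:
    """Score each component and set its rejection flag.

    A component is flagged when its 20–40 Hz band-power ratio, spatial
    concentration, or short-window power CV exceeds its threshold — unless
    the component's trial-averaged time course correlates with the grand
    evoked response above the protection threshold (evoked-looking
    components are never removed).
    """
    n_time = decomp.n_time
    grand_erp = epochs.data[decomp.trial_index].mean(axis=(0, 1))
    rows = []
    for k in range(decomp.n_components):
        src = decomp.sources[k]
        ratio = _band_power_ratio(src, epochs.fs)
        cv = _power_cv(src, epochs.fs)
        col = np.abs(decomp.mixing[:, k])
        conc = float(col.max() / col.sum()) if col.sum() > 0 else 0.0
        comp_erp = src.reshape(-1, n_time).mean(axis=0)
        if comp_erp.std() > 0 and grand_erp.std() > 0:
            erp_sim = float(abs(np.corrcoef(comp_erp, grand_erp)[0, 1]))
        else:
            erp_sim = 0.0
        rows.append((ratio, conc, cv, erp_sim))
    scores = pd.DataFrame(
        rows, columns=["band_ratio", "concentration", "power_cv", "erp_similarity"]
    )
    exceeds = (
        (scores["band_ratio"] > thresholds.band_ratio)
        | (scores["concentration"] > thresholds.concentration)
        | (scores["power_cv"] > thresholds.power_cv)
    )
    protected = scores["erp_similarity"] > thresholds.erp_protect
    flags = (exceeds & ~protected).to_numpy()
    return replace(decomp, scores=scores, flags=flags)


def remove_components(epochs: EpochedEEG,
                      decomp: ComponentDecomposition) -> EpochedEEG:
    """Reconstruct the accepted epochs with flagged components zeroed."""
    if decomp.flags is None:
        raise ValueError("component flags not set; run score_and_flag_components")
    if decomp.flags.all():
        raise ValueError("refusing to remove all components (empty reconstruction)")
    clean = decomp.reconstruct(keep=~decomp.flags)
    data = epochs.data.copy()
    n_ch, n_time = epochs.n_channels, decomp.n_time
    data[decomp.trial_index] = (
        clean.reshape(n_ch, len(decomp.trial_index), n_time).transpose(1, 0, 2)
    )
    return replace(epochs, data=data)
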