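"""Visual-evoked-potential quantification.

For each electrode, block and condition the evoked response is the mean over
accepted trials; the N70 trough is the minimum voltage in the 60–100 ms
window, the P100 peak the maximum in 90–130 ms, and the peak-to-peak
amplitude their difference. Electrode-mean peak-to-peak values are normalized
to the animal's light-only baseline block, and a laterality index compares
electrodes ipsilateral vs contralateral to the sonicated side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochedEEG
from .synth import Channel

__all__ = [
    "ERP",
    "VEPMeasure",
    "average_evoked",
    "peak_to_peak",
    "normalize_to_baseline",
    "laterality_index",
    "moving_average",
]


@dataclass
class ERP:
    """Trial-averaged evoked response: channels x time, µV."""

    data: np.ndarray
    time_ms: np.ndarray
    channels: tuple[Channel, ...]
    n_trials: int
    block: str | None = None
    condition: str | None = None


@dataclass
class VEPMeasure:
    """Peak measurements for one condition cell.

    ``table`` has one row per electrode (channel, n70_uV, n70_ms, p100_uV,
    p100_ms, p2p_uV); ``mean_p2p_uv`` is the electrode average, and
    ``normalized_p2p`` is filled by :func:`normalize_to_baseline`.
    """

    table: pd.DataFrame
    mean_p2p_uv: float
    block: str | None = None
    condition: str | None = None
    normalized_p2p: float | None = None


def average_evoked(epochs: EpochedEEG, block: str | None = None,
                   condition: str | None = None) -> ERP:
    """Per-channel mean over accepted trials in a condition cell."""
    data = epochs.accepted_data(block, condition)
    if data.shape[0] == 0:
        raise ValueError(f"no accepted trials in cell ({block}, {condition})")
    return ERP(
        data=data.mean(axis=0), time_ms=epochs.time_ms, channels=epochs.channels,
        n_trials=data.shape[0], block=block, condition=condition,
    )


def _window_extremum(trace: np.ndarray, time_ms: np.ndarray,
                     window: tuple[float, float], which: str) -> tuple[float, float]:
    mask = (time_ms >= window[0]) & (time_ms <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} ms lies outside the epoch time axis")
    seg = trace[mask]
    t = time_ms[mask]
    # argmin/argmax return the first occurrence: ties resolve to the
    # earliest latency.
    i = int(np.argmin(seg) if which == "min" else np.argmax(seg))
    return float(seg[i]), float(t[i])


def peak_to_peak(
    erp: ERP,
    n70_window: tuple[float, float] = (60.0, 100.0),
    p100_window: tuple[float, float] = (90.0, 130.0),
    channel_indices: np.ndarray | None = None,
) -> VEPMeasure:
    """N70/P100 detection and peak-to-peak amplitude per electrode.

    The trough is the in-window minimum and the peak the in-window maximum;
    the electrode mean of p2p is taken afterwards. ``channel_indices``
    restricts quantification to a subset of electrodes (default: all).
    """
    if channel_indices is None:
        channel_indices = np.arange(erp.data.shape[0])
    rows = []
    for i in channel_indices:
        n70_uv, n70_ms = _window_extremum(erp.data[i], erp.time_ms, n70_window, "min")
        p100_uv, p100_ms = _window_extremum(erp.data[i], erp.time_ms, p100_window, "max")
        assert n70_window[0] <= n70_ms <= n70_window[1]
        assert p100_window[0] <= p100_ms <= p100_window[1]
        rows.append((erp.channels[i].name, n70_uv, n70_ms, p100_uv, p100_ms,
                     p100_uv - n70_uv))
    table = pd.DataFrame(
        rows, columns=["channel", "n70_uV", "n70_ms", "p100_uV", "p100_ms", "p2p_uV"]
    )
    return VEPMeasure(
        table=table, mean_p2p_uv=float(table["p2p_uV"].mean()),
        block=erp.block, condition=erp.condition,
    )


def normalize_to_baseline(
    measures: dict[str, VEPMeasure],
    baseline_block: str = "Baseline",
    per_electrode: bool = False,
) -> dict[str, VEPMeasure]:
    """Normalize each block's peak-to-peak value to the baseline block.

    Default behaviour averages across electrodes first and then divides the
    electrode-mean p2p by the baseline's electrode-mean p2p (the baseline
    block normalizes to exactly 1). ``per_electrode=True`` instead normalizes
    each electrode by its own baseline p2p before averaging the ratios.
    """
    if baseline_block not in measures:
        raise ValueError(f"baseline block {baseline_block!r} missing from measures")
    base = measures[baseline_block]
    if base.mean_p2p_uv <= 0:
        raise ValueError("baseline peak-to-peak amplitude must be positive")
    out: dict[str, VEPMeasure] = {}
    for block, m in measures.items():
        if per_electrode:
            merged = m.table.merge(base.table[["channel", "p2p_uV"]],
                                   on="channel", suffixes=("", "_base"))
            if (merged["p2p_uV_base"] <= 0).any():
                raise ValueError("per-electrode baseline p2p must be positive")
            norm = float((merged["p2p_uV"] / merged["p2p_uV_base"]).mean())
        else:
            norm = m.mean_p2p_uv / base.mean_p2p_uv
        out[block] = VEPMeasure(
            table=m.table, mean_p2p_uv=m.mean_p2p_uv, block=m.block,
            condition=m.condition, normalized_p2p=norm,
        )
    return out


def laterality_index(measure: VEPMeasure, channels: tuple[Channel, ...],
                     sonicated_side: str) -> float:
    """Percent reduction of ipsilateral relative to contralateral occipital
    response: ``100 * (1 − mean p2p(ipsi) / mean p2p(contra))``.

    The sonication target projects to the ipsilateral hemisphere, so with a
    binocular stimulus a unilaterally suppressed thalamic relay should reduce
    ipsilateral electrodes more than contralateral ones.
    """
    if sonicated_side not in ("left", "right"):
        raise ValueError("sonicated_side must be 'left' or 'right'")
    name_to_side = {c.name: c.side for c in channels if c.region == "occipital"}
    tab = measure.table[measure.table["channel"].isin(name_to_side)]
    sides = tab["channel"].map(name_to_side)
    ipsi = tab.loc[(sides == sonicated_side).to_numpy(), "p2p_uV"]
    contra = tab.loc[(sides != sonicated_side).to_numpy(), "p2p_uV"]
    if len(ipsi) == 0 or len(contra) == 0:
        raise ValueError("need at least one occipital electrode on each side")
    return float(100.0 * (1.0 - ipsi.mean() / contra.mean()))


def moving_average(trace: np.ndarray, n_points: int = 15) -> np.ndarray:
    """Display-only smoothing used when plotting evoked traces (never applied
    before quantification). Centered boxcar with edge truncation."""
    kernel = np.ones(n_points)
    counts = np.convolve(np.ones_like(trace), kernel, mode="same")
    return np.convolve(trace, kernel, mode="same") / counts
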