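"""File dialects used by the pipeline.

EEG goes to a delimited text matrix (channels as columns, header row of
channel names) with a JSON sidecar carrying the sampling rate and channel
metadata; EDF files are readable when ``mne`` is available. Event tables are
TSV; epochs and spectrograms are HDF5; ARFI phase/displacement images are
NIfTI with a JSON sidecar for the encoding metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .arfi import EncodingParams
from .preprocess import EpochedEEG
from .spectral import Spectrogram
from .synth import Channel, RawEEG

__all__ = [
    "write_eeg",
    "read_eeg",
    "write_events",
    "read_events",
    "write_epochs",
    "read_epochs",
    "write_spectrogram",
    "read_spectrogram",
    "write_arfi_pair",
    "read_arfi_pair",
    "write_displacement",
]

EVENT_COLUMNS = ["onset_s", "block", "condition", "light_on", "tus_on"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_eeg(raw: RawEEG, path: str | Path) -> Path:
    """Write a recording as a TSV matrix (one column per channel, header row
    of channel names, µV) plus a JSON sidecar with fs and channel metadata.

    EDF output is not supported (requires an EDF writer backend); pass a
    ``.tsv``/``.txt``/``.csv`` path.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raise ValueError(
            "EDF writing is unavailable; write the delimited-text dialect "
            "(.tsv) instead"
        )
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(raw.data.T, columns=raw.channel_names())
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")
    meta = {
        "fs": raw.fs,
        "unit": "uV",
        "channels": [
            {"name": c.name, "region": c.region, "side": c.side,
             "distance_cm": c.distance_cm}
            for c in raw.channels
        ],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_eeg(path: str | Path, fs: float | None = None) -> RawEEG:
    """Read a recording from the delimited-text dialect or from EDF.

    For text files the JSON sidecar supplies fs and channel metadata; absent
    a sidecar, ``fs`` must be given and channels default to occipital/left.
    EDF reading requires the optional ``mne`` dependency.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        channels = tuple(
            Channel(name, "occipital", "left") for name in raw.ch_names
        )
        return RawEEG(data=raw.get_data() * 1e6, fs=raw.info["sfreq"],
                      channels=channels)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta["fs"]
        channels = tuple(
            Channel(c["name"], c["region"], c["side"], c.get("distance_cm", 5.0))
            for c in meta["channels"]
        )
    else:
        if fs is None:
            raise ValueError("no sidecar found; sampling rate fs is required")
        channels = tuple(Channel(n, "occipital", "left") for n in df.columns)
    return RawEEG(data=df.to_numpy().T, fs=fs, channels=channels)


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table is missing columns {sorted(missing)}")
    return events[EVENT_COLUMNS].astype(
        {"onset_s": float, "light_on": bool, "tus_on": bool}
    )


def write_epochs(epochs: EpochedEEG, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset("mask", data=epochs.accepted)
        lab = f.create_group("labels")
        for col in EVENT_COLUMNS:
            vals = epochs.labels[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                vals = np.array([str(v) for v in vals], dtype="S32")
            lab.create_dataset(col, data=vals)
        ch = f.create_group("channels")
        ch.attrs["name"] = [c.name for c in epochs.channels]
        ch.attrs["region"] = [c.region for c in epochs.channels]
        ch.attrs["side"] = [c.side for c in epochs.channels]
        ch.attrs["distance_cm"] = [c.distance_cm for c in epochs.channels]
        f.attrs["fs"] = epochs.fs
    return path


def read_epochs(path: str | Path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        time_ms = f["time_ms"][()]
        accepted = f["mask"][()].astype(bool)
        labels = {}
        for col in EVENT_COLUMNS:
            vals = f["labels"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            labels[col] = vals
        ch = f["channels"]
        channels = tuple(
            Channel(str(n), str(r), str(s), float(d))
            for n, r, s, d in zip(ch.attrs["name"], ch.attrs["region"],
                                  ch.attrs["side"], ch.attrs["distance_cm"])
        )
        fs = float(f.attrs["fs"])
    return EpochedEEG(
        data=data, fs=fs, time_ms=time_ms, labels=pd.DataFrame(labels),
        channels=channels, accepted=accepted,
    )


def write_spectrogram(spec: Spectrogram, path: str | Path,
                      name: str = "spectrogram") -> Path:
    path = Path(path)
    mode = "a" if path.exists() else "w"
    with h5py.File(path, mode) as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("power", data=spec.power, compression="gzip")
        g.create_dataset("freqs_hz", data=spec.freqs_hz)
        g.create_dataset("time_ms", data=spec.time_ms)
        g.attrs["kind"] = spec.kind
        g.attrs["units"] = spec.units
        if spec.baseline_window_ms is not None:
            g.attrs["baseline_window_ms"] = spec.baseline_window_ms
    return path


def read_spectrogram(path: str | Path, name: str = "spectrogram") -> Spectrogram:
    with h5py.File(path, "r") as f:
        g = f[name]
        baseline = g.attrs.get("baseline_window_ms")
        return Spectrogram(
            power=g["power"][()], freqs_hz=g["freqs_hz"][()],
            time_ms=g["time_ms"][()], kind=str(g.attrs["kind"]),
            units=str(g.attrs["units"]),
            baseline_window_ms=tuple(baseline) if baseline is not None else None,
        )


def _nifti(data: np.ndarray):
    import nibabel as nib

    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))


def write_arfi_pair(phase_plus: np.ndarray, phase_minus: np.ndarray,
                    encoding: EncodingParams, stem: str | Path) -> tuple[Path, Path, Path]:
    """Write phase images (float32 radians) as NIfTI plus a JSON metadata
    sidecar with the encoding parameters."""
    import nibabel as nib

    stem = Path(stem)
    plus = stem.with_name(stem.name + "_plus.nii")
    minus = stem.with_name(stem.name + "_minus.nii")
    meta = stem.with_name(stem.name + "_encoding.json")
    nib.save(_nifti(phase_plus), plus)
    nib.save(_nifti(phase_minus), minus)
    meta.write_text(json.dumps({
        "G_T_per_m": encoding.G_T_per_m,
        "tau_s": encoding.tau_s,
        "gamma_rad_per_s_per_T": encoding.gamma_rad_per_s_per_T,
        "polarity": list(encoding.polarity_labels),
    }, indent=1))
    return plus, minus, meta


def read_arfi_pair(plus: str | Path, minus: str | Path, meta: str | Path):
    import nibabel as nib

    from .arfi import ARFIPair

    md = json.loads(Path(meta).read_text())
    enc = EncodingParams(
        G_T_per_m=md["G_T_per_m"], tau_s=md["tau_s"],
        gamma_rad_per_s_per_T=md.get(
            "gamma_rad_per_s_per_T", EncodingParams.gamma_rad_per_s_per_T
        ),
        polarity_labels=tuple(md.get("polarity", ("plus", "minus"))),
    )
    p = np.asarray(nib.load(plus).dataobj, dtype=float)
    m = np.asarray(nib.load(minus).dataobj, dtype=float)
    return ARFIPair(phase_plus=p, phase_minus=m, encoding=enc)


def write_displacement(D_um: np.ndarray, path: str | Path) -> Path:
    import nibabel as nib

    path = Path(path)
    nib.save(_nifti(D_um), path)
    return path
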