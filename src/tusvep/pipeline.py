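"""End-to-end orchestration of a simulated TUS-VEP study.

One :class:`RunConfig` describes a cohort of experiments (sonication group,
focal displacement, suppression coupling) together with the analysis
parameters of every stage. :func:`run_study` simulates each experiment,
preprocesses, quantifies VEPs per block, decomposes spectra, runs the
permutation difference map and the group t tests, computes the ARFI
dose-response, and writes an output tree with a checksummed run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, arfi, io, spectral, stats, synth, vep
from .preprocess import (
    ComponentThresholds,
    EpochedEEG,
    bandpass,
    decompose_components,
    epoch,
    equalize_trials,
    reject_amplitude_artifacts,
    remove_components,
    score_and_flag_components,
)

__all__ = ["ExperimentSpec", "RunConfig", "RunManifest", "default_run_config",
           "load_run_config", "run_study", "report"]

logger = logging.getLogger(__name__)

SONICATION_BLOCKS = ("LGN1", "LGN2")
CONTROL_BLOCKS = ("Ctrl1", "Ctrl2", "Ctrl3")


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment of the cohort.

    ``displacement_peak_um`` is the focal ARFI displacement for this animal;
    in the LGN-TUS group the evoked suppression is derived from it through
    the run's coupling rule. Sham experiments keep suppression at 1 (the
    transducer was off target or off), with a small off-target displacement.
    """

    name: str
    group: str  # "LGN-TUS" | "ActiveSham" | "NoFUS"
    displacement_peak_um: float | None = None
    sonicated_side: str = "left"

    def __post_init__(self) -> None:
        if self.group not in ("LGN-TUS", "ActiveSham", "NoFUS"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class RunConfig:
    """Study configuration: cohort plus per-stage analysis parameters."""

    experiments: list[ExperimentSpec]
    seed: int = 0
    # schedule (sections are one-minute units; study values: 5 / 20)
    baseline_sections: int = 5
    block_sections: int = 20
    n_trials: int = 250
    # suppression coupling: s = 1 - coupling * d / displacement_ref_um
    coupling: float = 0.5
    displacement_ref_um: float = 2.0
    # preprocessing
    reject_threshold_uv: float = 100.0
    ica_thresholds: ComponentThresholds = field(default_factory=ComponentThresholds)
    run_ica: bool = True
    # spectral / stats
    n_perm: int = 500
    alpha: float = 0.05
    time_decim: int = 4
    # ARFI
    arfi_tau_s: float = 3e-3
    arfi_noise_sd_rad: float = 2e-3
    arfi_grid: tuple[int, int, int] = (33, 33, 33)
    arfi_fwhm_mm: float = 4.0
    # simulator overrides
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("experiment groups must be non-empty")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict
    timestamps: dict
    warnings: list


def default_run_config(seed: int = 0, scale: str = "small") -> RunConfig:
    """A ready-to-run synthetic cohort.

    ``scale="small"`` shrinks the schedule (4 sections per block, 60
    equalized trials) for quick runs; ``scale="study"`` uses the full
    5/20-minute blocks and 250 trials.
    """
    if scale == "small":
        kw = dict(baseline_sections=4, block_sections=4, n_trials=50,
                  n_perm=200)
    elif scale == "study":
        kw = dict(baseline_sections=5, block_sections=20, n_trials=250)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    rng = np.random.default_rng(seed)
    experiments = [
        ExperimentSpec(f"lgn{i+1}", "LGN-TUS",
                       displacement_peak_um=float(rng.uniform(0.6, 2.0)))
        for i in range(3)
    ] + [
        ExperimentSpec("sham1", "ActiveSham", displacement_peak_um=0.15),
        ExperimentSpec("sham2", "NoFUS", displacement_peak_um=None),
    ]
    return RunConfig(experiments=experiments, seed=seed, **kw)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a TOML file (unknown keys rejected)."""
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    exps = [ExperimentSpec(**e) for e in raw.pop("experiments")]
    sim_raw = raw.pop("sim", None)
    ica_raw = raw.pop("ica_thresholds", None)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(experiments=exps, **raw)
    if sim_raw is not None:
        cfg.sim = synth.SimConfig(**sim_raw)
    if ica_raw is not None:
        cfg.ica_thresholds = ComponentThresholds(**ica_raw)
    return cfg


def _suppression_for(exp: ExperimentSpec, cfg: RunConfig) -> float:
    if exp.group != "LGN-TUS" or exp.displacement_peak_um is None:
        return 1.0
    s = 1.0 - cfg.coupling * exp.displacement_peak_um / cfg.displacement_ref_um
    return float(np.clip(s, 0.0, 1.0))


def clean_tus_conditions(epochs: EpochedEEG,
                         thresholds: ComponentThresholds,
                         seed: int = 0) -> EpochedEEG:
    """ICA-clean the TUS-containing conditions only (light-only trials are
    left untouched, mirroring the study's artifact-removal scope)."""
    tus_mask = epochs.labels["tus_on"].to_numpy(dtype=bool)
    if not tus_mask.any():
        return epochs
    sub = epochs.select(tus_mask)
    decomp = decompose_components(sub, seed=seed)
    decomp = score_and_flag_components(decomp, sub, thresholds)
    if decomp.flags is not None and decomp.flags.all():
        warnings.warn("all ICA components flagged; skipping removal", stacklevel=2)
        return epochs
    cleaned = remove_components(sub, decomp)
    data = epochs.data.copy()
    data[tus_mask] = cleaned.data
    out = epochs
    out = EpochedEEG(data=data, fs=epochs.fs, time_ms=epochs.time_ms,
                     labels=epochs.labels, channels=epochs.channels,
                     accepted=epochs.accepted)
    return out


def _preprocess_experiment(exp: ExperimentSpec, cfg: RunConfig,
                           exp_seed: int) -> EpochedEEG:
    blocks = [("Baseline", cfg.baseline_sections)] + [
        (b, cfg.block_sections) for b in SONICATION_BLOCKS + CONTROL_BLOCKS
    ]
    suppression = {b: _suppression_for(exp, cfg) for b in SONICATION_BLOCKS}
    sim = synth.SimConfig(
        seed=exp_seed,
        channels=cfg.sim.channels,
        fs=cfg.sim.fs,
        evoked=cfg.sim.evoked,
        noise_scale_uv=cfg.sim.noise_scale_uv,
        gamma_burst=cfg.sim.gamma_burst,
        suppression=suppression,
        frontal_gain=cfg.sim.frontal_gain,
        tus_artifact=cfg.sim.tus_artifact,
        blink=cfg.sim.blink,
    )
    events = synth.make_event_table(sim, blocks)
    raw = synth.simulate_eeg(events, sim)
    raw = bandpass(raw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epochs = epoch(raw, events)
        epochs = reject_amplitude_artifacts(epochs, cfg.reject_threshold_uv)
        epochs = equalize_trials(epochs, n=cfg.n_trials)
        if cfg.run_ica:
            epochs = clean_tus_conditions(epochs, cfg.ica_thresholds,
                                          seed=exp_seed)
    return epochs


def _checksum(path: Path) -> str:
    """Content checksum; HDF5 files are hashed over their logical dataset
    contents (file bytes carry write timestamps)."""
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        h = hashlib.sha256()
        with h5py.File(path, "r") as f:
            names: list[str] = []
            f.visit(names.append)
            for name in sorted(names):
                obj = f[name]
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
        return h.hexdigest()
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the full study replica and write the output tree.

    Produces ``vep.csv`` (per-electrode and normalized block measures),
    ``erp_traces.csv``, per-experiment spectrogram HDF5 files, a permutation
    difference-map HDF5, ``arfi.csv``, ``dose_response.csv``, ``ttests.csv``
    and ``manifest.json``. Returns a dict of the main result objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    run_warnings: list[str] = []
    family = spectral.build_wavelets(cfg.sim.fs)

    vep_rows, erp_rows, arfi_rows = [], [], []
    spectra_files = []
    diff_result = None
    for i, exp in enumerate(cfg.experiments):
        exp_seed = cfg.seed * 10007 + i
        stage = f"preprocess[{exp.name}]"
        try:
            epochs = _preprocess_experiment(exp, cfg, exp_seed)
        except Exception as e:  # pragma: no cover - defensive
            raise RuntimeError(f"stage {stage} failed: {e}") from e

        occ = epochs.channel_indices(region="occipital")
        # --- VEP per block, light-only trials -------------------------------
        measures = {}
        for block in ("Baseline",) + SONICATION_BLOCKS + CONTROL_BLOCKS:
            erp = vep.average_evoked(epochs, block=block, condition="light")
            measures[block] = vep.peak_to_peak(erp)
            trace = erp.data[occ].mean(axis=0)
            erp_rows.append(pd.DataFrame({
                "experiment": exp.name, "group": exp.group, "block": block,
                "time_ms": erp.time_ms, "mean_uV": trace,
            }))
        measures = vep.normalize_to_baseline(measures)
        for block, m in measures.items():
            for row in m.table.itertuples(index=False):
                vep_rows.append({
                    "experiment": exp.name, "group": exp.group, "block": block,
                    "condition": "light", "electrode": row.channel,
                    "n70_uV": row.n70_uV, "n70_ms": row.n70_ms,
                    "p100_uV": row.p100_uV, "p100_ms": row.p100_ms,
                    "p2p_uV": row.p2p_uV, "normalized_p2p": m.normalized_p2p,
                })

        # --- spectra: light vs light+TUS in the first sonication block ------
        spec_path = out / f"spectra_{exp.name}.h5"
        occ_mean = lambda cond: epochs.accepted_data("LGN1", cond)[:, occ, :].mean(axis=1)  # noqa: E731
        try:
            total = spectral.total_power(epochs, family, "LGN1", "light",
                                         channel_indices=occ)
            npl = spectral.npl_power(epochs, family, "LGN1", "light",
                                     channel_indices=occ)
            pl = spectral.pl_power(total, npl)
            for name, s in (("total", total), ("npl", npl), ("pl", pl)):
                io.write_spectrogram(spectral.db_baseline(s), spec_path,
                                     name=f"light/{name}")
            spectra_files.append(spec_path)
            if i == 0:
                trials_tus = occ_mean("light+tus")
                trials_light = occ_mean("light")
                a = trials_tus - trials_tus.mean(axis=0, keepdims=True)
                b = trials_light - trials_light.mean(axis=0, keepdims=True)
                diff_result = stats.permutation_diff_map(
                    a, b, family, epochs.time_ms, n_perm=cfg.n_perm,
                    alpha=cfg.alpha, seed=cfg.seed, time_decim=cfg.time_decim,
                )
        except ValueError as e:
            msg = f"spectral stage skipped for {exp.name}: {e}"
            run_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

        # --- ARFI ------------------------------------------------------------
        if exp.displacement_peak_um is not None:
            enc = arfi.EncodingParams(tau_s=cfg.arfi_tau_s)
            shape = cfg.arfi_grid
            center = tuple((n - 1) / 2.0 for n in shape)
            field_m = synth.gaussian_focus(shape, 1.0, center, cfg.arfi_fwhm_mm,
                                           exp.displacement_peak_um * 1e-6)
            plus, minus = synth.simulate_arfi_pair(
                field_m, enc, noise_sd_rad=cfg.arfi_noise_sd_rad, seed=exp_seed)
            pair = arfi.ARFIPair(plus, minus, enc)
            dmap = arfi.displacement_map(arfi.phase_difference(pair), enc)
            roi = field_m > field_m.max() * 0.05
            mx = arfi.max_displacement(dmap, roi=roi)
            arfi_rows.append({
                "experiment": exp.name, "group": exp.group,
                "max_um": mx.value_um, "x": mx.index[0], "y": mx.index[1],
                "z": mx.index[2], "detectable": mx.detectable,
            })
        else:
            msg = f"no ARFI inputs for {exp.name}; displacement skipped"
            run_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

    vep_table = pd.DataFrame(vep_rows)
    vep_table.to_csv(out / "vep.csv", index=False, float_format="%.6f")
    pd.concat(erp_rows, ignore_index=True).to_csv(
        out / "erp_traces.csv", index=False, float_format="%.6f")
    arfi_table = pd.DataFrame(arfi_rows)
    arfi_table.to_csv(out / "arfi.csv", index=False, float_format="%.6f")
    if diff_result is not None:
        _write_diffmap(diff_result, out / "diffmap_npl.h5")

    # --- group statistics ----------------------------------------------------
    summary = (
        vep_table.groupby(["experiment", "group", "block"], as_index=False)
        .agg(normalized_p2p=("normalized_p2p", "first"))
    )
    test_rows = []
    for design in ("baseline-vs-lgn-paired", "lgn-vs-sham-unpaired"):
        try:
            r = stats.t_tests(summary, design)
            test_rows.append({"design": design, "t": r.t, "df": r.df, "p": r.p,
                              "alternative": r.alternative})
        except (ValueError, KeyError) as e:
            msg = f"t-test {design} skipped: {e}"
            run_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    pd.DataFrame(test_rows).to_csv(out / "ttests.csv", index=False,
                                   float_format="%.6g")

    dr = None
    lgn = summary[(summary["group"] == "LGN-TUS")
                  & summary["block"].isin(SONICATION_BLOCKS)]
    lgn_mean = lgn.groupby("experiment")["normalized_p2p"].mean()
    if len(arfi_table):
        merged = arfi_table[arfi_table["experiment"].isin(lgn_mean.index)]
        if len(merged) >= 3:
            dr = stats.dose_response(
                merged.set_index("experiment")["max_um"].loc[lgn_mean.index[
                    lgn_mean.index.isin(merged["experiment"])]].to_numpy(),
                lgn_mean[lgn_mean.index.isin(merged["experiment"])].to_numpy(),
            )
            pd.DataFrame([asdict(dr)]).to_csv(out / "dose_response.csv",
                                              index=False, float_format="%.6g")
    if dr is None:
        msg = "dose-response stage skipped (insufficient ARFI data)"
        run_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    # --- manifest -------------------------------------------------------------
    cfg_json = json.dumps(_config_dict(cfg), sort_keys=True, default=str)
    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=__version__,
        checksums={p.name: _checksum(p) for p in outputs},
        timestamps={"started": t_start, "finished": time.time()},
        warnings=run_warnings,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=1))
    return {"vep": vep_table, "arfi": arfi_table, "dose_response": dr,
            "diffmap": diff_result, "tests": test_rows, "manifest": manifest}


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["sim"]["suppression"] = dict(d["sim"].get("suppression", {}))
    return d


def _write_diffmap(result, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("difference_db", data=result.difference_db)
        f.create_dataset("p", data=result.p)
        f.create_dataset("mask", data=result.mask)
        f.create_dataset("freqs_hz", data=result.freqs_hz)
        f.create_dataset("time_ms", data=result.time_ms)
        f.attrs["alpha"] = result.alpha
        f.attrs["n_permutations"] = result.n_permutations
        f.attrs["seed"] = result.seed


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def report(run_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Render summary figures from a run's output tree.

    Five panel families: ERP overlays (display-smoothed), block-wise
    normalized amplitude lines, spectrogram panels, the difference map with
    its significance contour, and the displacement-vs-VEP scatter. Missing
    inputs skip their panel with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir else run_dir / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _skip(panel: str, why: str) -> None:
        warnings.warn(f"panel {panel} skipped: {why}", stacklevel=3)

    erp_path = run_dir / "erp_traces.csv"
    if erp_path.exists():
        erps = pd.read_csv(erp_path)
        if len(erps):
            fig, ax = plt.subplots(figsize=(6, 4))
            first = erps[erps["experiment"] == erps["experiment"].iloc[0]]
            for block in ("Baseline", "LGN1", "Ctrl1"):
                sub = first[first["block"] == block]
                if len(sub):
                    ax.plot(sub["time_ms"],
                            vep.moving_average(sub["mean_uV"].to_numpy()),
                            label=block)
            ax.set(xlabel="time (ms)", ylabel="µV", title="evoked responses")
            ax.legend()
            p = out / "erp_overlay.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
        else:
            _skip("erp_overlay", "empty ERP table")
    else:
        _skip("erp_overlay", "erp_traces.csv missing")

    vep_path = run_dir / "vep.csv"
    if vep_path.exists() and len(v := pd.read_csv(vep_path)):
        fig, ax = plt.subplots(figsize=(6, 4))
        summary = v.groupby(["experiment", "block"], as_index=False).agg(
            norm=("normalized_p2p", "first"))
        order = ["Baseline", "LGN1", "LGN2", "Ctrl1", "Ctrl2", "Ctrl3"]
        for name, sub in summary.groupby("experiment"):
            sub = sub.set_index("block").reindex(order)
            ax.plot(order, sub["norm"], marker="o", label=name)
        ax.set(ylabel="normalized p2p", title="VEP amplitude by block")
        ax.legend(fontsize=7)
        p = out / "vep_blocks.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    else:
        _skip("vep_blocks", "vep.csv missing or empty")

    spec_files = sorted(run_dir.glob("spectra_*.h5"))
    if spec_files:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        for ax, kind in zip(axes, ("total", "npl", "pl")):
            s = io.read_spectrogram(spec_files[0], name=f"light/{kind}")
            im = ax.pcolormesh(s.time_ms, s.freqs_hz, s.power, shading="auto",
                               cmap="RdBu_r")
            ax.set(title=f"{kind} (dB)", xlabel="time (ms)", ylabel="Hz")
            fig.colorbar(im, ax=ax)
        p = out / "spectrograms.png"
        fig.tight_layout()
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    else:
        _skip("spectrograms", "no spectra files")

    diff_path = run_dir / "diffmap_npl.h5"
    if diff_path.exists():
        import h5py

        with h5py.File(diff_path, "r") as f:
            d = f["difference_db"][()]
            mask = f["mask"][()]
            freqs = f["freqs_hz"][()]
            t = f["time_ms"][()]
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.pcolormesh(t, freqs, d, shading="auto", cmap="RdBu_r")
        if mask.any():
            ax.contour(t, freqs, mask.astype(float), levels=[0.5], colors="k")
        ax.set(xlabel="time (ms)", ylabel="Hz",
               title="NPL difference (light+TUS − light)")
        fig.colorbar(im, ax=ax)
        p = out / "diffmap.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    else:
        _skip("diffmap", "diffmap_npl.h5 missing")

    dr_path = run_dir / "dose_response.csv"
    arfi_path = run_dir / "arfi.csv"
    if dr_path.exists() and arfi_path.exists() and vep_path.exists():
        a = pd.read_csv(arfi_path)
        v = pd.read_csv(vep_path)
        lgn = v[v["block"].isin(SONICATION_BLOCKS) & (v["group"] == "LGN-TUS")]
        norm = lgn.groupby("experiment")["normalized_p2p"].mean()
        merged = a[a["experiment"].isin(norm.index)]
        if len(merged) >= 2:
            x = merged.set_index("experiment")["max_um"]
            y = norm.loc[x.index]
            slope, intercept = np.polyfit(x, y, 1)
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(x, y)
            xs = np.linspace(x.min(), x.max(), 10)
            ax.plot(xs, slope * xs + intercept, "k--",
                    label=f"slope {slope:.2f}")
            ax.set(xlabel="max displacement (µm)", ylabel="normalized p2p",
                   title="dose-response")
            ax.legend()
            p = out / "dose_response.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
        else:
            _skip("dose_response", "too few paired points")
    else:
        _skip("dose_response", "dose-response outputs missing")

    return written
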