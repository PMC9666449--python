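"""Statistics: permutation difference maps on spectrograms, the study's
t-test comparisons, and the displacement–suppression dose-response
correlation.

The permutation test compares two trial sets pixel-by-pixel in
time–frequency space. The observed statistic is the difference of the two
conditions' baselined (dB) mean spectrograms; the null is built by
re-assigning trials to conditions at random and recomputing the difference.
Two-sided p-values use the add-one convention,
``p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)``, and — matching the study —
no multiple-comparison correction is applied by default.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .spectral import WaveletFamily, single_trial_power

__all__ = [
    "DiffMapResult",
    "permutation_diff_map",
    "TTestResult",
    "paired_t",
    "unpaired_t",
    "one_sample_t",
    "t_tests",
    "DoseResponse",
    "dose_response",
]


@dataclass
class DiffMapResult:
    """Permutation difference-map result.

    ``difference_db`` is mean dB spectrogram(A) − mean dB spectrogram(B);
    ``p`` the per-pixel two-sided permutation p-value; ``mask`` the
    uncorrected ``p < alpha`` significance mask.
    """

    difference_db: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    freqs_hz: np.ndarray
    time_ms: np.ndarray
    alpha: float
    n_permutations: int
    seed: int


def _db_of_mean(mean_power: np.ndarray, base_cols: np.ndarray) -> np.ndarray:
    """dB map(s) of mean power (..., F, T) against the per-frequency mean
    over the baseline columns."""
    base = mean_power[..., base_cols].mean(axis=-1, keepdims=True)
    return 10.0 * np.log10(mean_power / base)


def _canonical_order(trials: np.ndarray) -> np.ndarray:
    """Deterministic, label-independent ordering of pooled trials (sorted by
    a content hash of each trial's bytes), so the permutation null depends
    only on the pooled trial multiset, not on which condition came first."""
    digests = [hashlib.sha1(np.ascontiguousarray(t).tobytes()).digest()
               for t in trials]
    return np.asarray(sorted(range(len(digests)), key=digests.__getitem__))


def permutation_diff_map(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    family: WaveletFamily,
    time_ms: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    baseline_window_ms: tuple[float, float] = (-150.0, 0.0),
    time_decim: int = 1,
    cluster_correction: bool = False,
) -> DiffMapResult:
    """Nonparametric permutation statistics on the A−B spectral difference.

    ``trials_a`` / ``trials_b`` are (n_trials, n_time) voltage arrays (single
    channel or channel-averaged). Per-trial power is computed once; each
    permutation shuffles the trial-to-condition assignment and recomputes the
    dB difference map. ``time_decim`` subsamples the time axis of the power
    maps to bound memory. Deterministic given ``seed``.

    ``cluster_correction=True`` additionally prunes the significance mask to
    clusters whose size exceeds the permutation 95th percentile of maximal
    null cluster sizes (off by default; the study applied no correction).
    """
    trials_a = np.atleast_2d(np.asarray(trials_a, float))
    trials_b = np.atleast_2d(np.asarray(trials_b, float))
    if trials_a.shape[0] < 2 or trials_b.shape[0] < 2:
        raise ValueError("each condition needs at least 2 trials")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for stable tail estimates")

    n_a, n_b = trials_a.shape[0], trials_b.shape[0]
    pool = np.concatenate([trials_a, trials_b], axis=0)
    power = single_trial_power(pool, family)[:, :, ::time_decim]
    t_axis = np.asarray(time_ms)[::time_decim]
    base_cols = np.where(
        (t_axis >= baseline_window_ms[0]) & (t_axis <= baseline_window_ms[1])
    )[0]
    if base_cols.size == 0:
        raise ValueError("baseline window lies outside the time axis")

    obs = (
        _db_of_mean(power[:n_a].mean(axis=0), base_cols)
        - _db_of_mean(power[n_a:].mean(axis=0), base_cols)
    )

    # Null: random splits of the canonically ordered pool into groups of the
    # observed sizes. Canonical ordering makes the null invariant to the
    # order in which the two conditions were passed in.
    order = _canonical_order(pool)
    n, F, T = power.shape
    X = power[order].reshape(n, F * T).astype(np.float32)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(obs).reshape(F * T)
    exceed = np.zeros(F * T, dtype=np.int64)
    max_cluster_sizes = [] if cluster_correction else None
    chunk = max(1, int(2.5e7 // (F * T)))  # bound transient memory
    perms_left = n_perm
    while perms_left > 0:
        m = min(chunk, perms_left)
        R = np.zeros((m, n), dtype=np.float32)
        for j in range(m):
            R[j, rng.permutation(n)[:n_a]] = 1.0
        s1 = (R @ X) / n_a
        s2 = ((1.0 - R) @ X) / n_b
        d = (
            _db_of_mean(s1.reshape(m, F, T), base_cols)
            - _db_of_mean(s2.reshape(m, F, T), base_cols)
        ).reshape(m, F * T)
        exceed += (np.abs(d) >= abs_obs).sum(axis=0)
        if cluster_correction:
            from scipy import ndimage

            for j in range(m):
                sig = (np.abs(d[j]).reshape(F, T) >= np.quantile(np.abs(d[j]), 0.95))
                lab, n_lab = ndimage.label(sig)
                sizes = ndimage.sum(sig, lab, range(1, n_lab + 1)) if n_lab else [0]
                max_cluster_sizes.append(int(np.max(sizes)))
        perms_left -= m

    p = ((1 + exceed) / (n_perm + 1)).reshape(F, T)
    mask = p < alpha
    if cluster_correction:
        from scipy import ndimage

        thresh = np.quantile(max_cluster_sizes, 0.95)
        lab, n_lab = ndimage.label(mask)
        for k in range(1, n_lab + 1):
            if (lab == k).sum() <= thresh:
                mask[lab == k] = False
    return DiffMapResult(
        difference_db=obs, p=p, mask=mask, freqs_hz=family.freqs_hz,
        time_ms=t_axis, alpha=alpha, n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    kind: str
    alternative: str


def _one_sided_from_t(t: float, df: float, alternative: str) -> float:
    if alternative == "greater":
        return float(sp_stats.t.sf(t, df))
    if alternative == "less":
        return float(sp_stats.t.cdf(t, df))
    return float(2 * sp_stats.t.sf(abs(t), df))


def _t_from_diffs(d: np.ndarray, kind: str, alternative: str) -> TTestResult:
    """One-sample t on a difference vector, with degenerate zero-variance
    cases resolved by convention: all-zero differences give t=0, p=0.5
    (one-sided); equal nonzero differences give t=±inf with p at the bound."""
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    mean = d.mean()
    df = n - 1
    if sd == 0:
        if mean == 0:
            t = 0.0
            p = 0.5 if alternative in ("greater", "less") else 1.0
        else:
            t = np.inf if mean > 0 else -np.inf
            p = _one_sided_from_t(t, df, alternative)
        return TTestResult(t=float(t), df=df, p=float(p), kind=kind,
                           alternative=alternative)
    t = mean / (sd / np.sqrt(n))
    return TTestResult(t=float(t), df=df, p=_one_sided_from_t(t, df, alternative),
                       kind=kind, alternative=alternative)


def paired_t(x, y, alternative: str = "greater") -> TTestResult:
    """Paired t test on x − y (default alternative: mean(x) > mean(y), the
    direction of baseline > suppressed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return _t_from_diffs(x - y, "paired", alternative)


def one_sample_t(x, popmean: float = 0.0,
                 alternative: str = "greater") -> TTestResult:
    return _t_from_diffs(np.asarray(x, float) - popmean, "one-sample", alternative)


def unpaired_t(x, y, alternative: str = "less") -> TTestResult:
    """Two-sample (Student) t test (default alternative: mean(x) < mean(y),
    the direction of suppressed group < sham)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1 / nx + 1 / ny))
    if denom == 0:
        diff = x.mean() - y.mean()
        t = 0.0 if diff == 0 else (np.inf if diff > 0 else -np.inf)
        p = (0.5 if diff == 0 and alternative in ("greater", "less")
             else _one_sided_from_t(t, df, alternative))
        if diff == 0 and alternative == "two-sided":
            p = 1.0
        return TTestResult(t=float(t), df=df, p=float(p), kind="unpaired",
                           alternative=alternative)
    t = (x.mean() - y.mean()) / denom
    return TTestResult(t=float(t), df=df, p=_one_sided_from_t(t, df, alternative),
                       kind="unpaired", alternative=alternative)


def t_tests(vep_table, design: str,
            baseline_block: str = "Baseline",
            lgn_blocks: tuple[str, ...] = ("LGN1", "LGN2"),
            value_col: str = "normalized_p2p") -> TTestResult:
    """Run one of the study's comparisons on a tidy per-experiment table.

    ``vep_table`` needs columns ``experiment, group, block`` and
    ``value_col``. Designs:

    * ``"baseline-vs-lgn-paired"`` — within LGN-group experiments, paired
      one-tailed test of baseline > mean(LGN blocks);
    * ``"lgn-vs-sham-unpaired"`` — LGN-group vs sham-group LGN-block values,
      one-tailed LGN < sham;
    * ``"laterality-one-sample"`` — per-experiment laterality percentages
      against 0, one-tailed > 0 (``value_col`` holds the percentages).
    """
    if design == "baseline-vs-lgn-paired":
        sub = vep_table[vep_table["group"] == "LGN-TUS"]
        piv = sub.pivot_table(index="experiment", columns="block",
                              values=value_col)
        base = piv[baseline_block].to_numpy()
        lgn = piv[list(lgn_blocks)].mean(axis=1).to_numpy()
        return paired_t(base, lgn, alternative="greater")
    if design == "lgn-vs-sham-unpaired":
        sub = vep_table[vep_table["block"].isin(lgn_blocks)]
        agg = sub.groupby(["experiment", "group"])[value_col].mean().reset_index()
        x = agg.loc[agg["group"] == "LGN-TUS", value_col].to_numpy()
        y = agg.loc[agg["group"] != "LGN-TUS", value_col].to_numpy()
        return unpaired_t(x, y, alternative="less")
    if design == "laterality-one-sample":
        vals = vep_table[value_col].to_numpy(dtype=float)
        return one_sample_t(vals, popmean=0.0, alternative="greater")
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponse:
    """Displacement vs normalized-VEP correlation. Greater focal displacement
    should suppress the VEP more, so the expected sign of ``pearson_r``
    (displacement vs normalized amplitude) is negative."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def dose_response(displacement_um, normalized_vep) -> DoseResponse:
    """Pearson and Spearman correlation of maximum focal displacement (µm)
    against baseline-normalized VEP amplitude, across experiments."""
    x = np.asarray(displacement_um, float)
    y = np.asarray(normalized_vep, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    pr = sp_stats.pearsonr(x, y)
    sr = sp_stats.spearmanr(x, y)
    return DoseResponse(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        n=len(x),
    )
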