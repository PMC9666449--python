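# Methods notes

This note records the models implemented in `tusvep`, the defaults and why
they were chosen, the numerical decisions that make results reproducible,
and what the synthetic-data generator does and does not emulate.

## Experimental schedule

The simulated study timeline mirrors a six-block design: a 5-minute
light-only baseline, two 20-minute sonication blocks on the visual-thalamus
target (LGN1, LGN2), then three 20-minute blocks on an off-target control
site (Ctrl1–3). Each sonication block is divided into one-minute sections of
four 15-second conditions — no stimulus, light only, TUS only, and
light+TUS — with stimuli repeating at 1 Hz, so each stimulus condition
contributes 15 trials per section (300 light-only trials per 20-minute
block). `make_event_table` accepts `(label, n_sections)` pairs so tests and
quick runs can shrink blocks without changing their structure. The simulated
timeline uses fixed inter-block gaps; variable gaps (and hence questions
about how long suppression outlasts sonication) are out of scope.

## Signal model of the generator

Each channel is a sum of independent components, all drawn from a single
seeded `numpy.random.Generator` so that identical configurations are
bit-identical:

* **Evoked response.** A two-lobe template: a negative Gaussian lobe at the
  N70 latency (default 80 ms, −15 µV) and a positive lobe at the P100
  latency (default 110 ms, +20 µV), each with 12 ms SD. A sum of two
  Gaussian-windowed lobes is the simplest waveform carrying exactly the two
  features the quantification measures; the defaults place both peaks
  centrally in their detection windows and produce a ~26 µV electrode-mean
  peak-to-peak amplitude, a plausible magnitude for a large-animal flash
  VEP. The template rides on occipital channels at full amplitude and on
  frontal channels at a volume-conduction gain of 0.4. The frontal copy is
  deliberate: the quantification averages peak-to-peak values across *all*
  electrodes, and if frontal channels carried only noise their noise-floor
  peak-to-peak would bias the normalized ratio upward at strong suppression;
  with an attenuated common copy the multiplicative suppression survives
  electrode averaging exactly.
* **Suppression.** A per-block factor in [0, 1] multiplies the evoked
  amplitude (optionally per hemisphere, for laterality experiments). This is
  the ground truth the VEP chain must recover.
* **Background noise.** 1/f-power (pink) noise, default 12 µV RMS per
  channel, produced by spectral shaping of white noise. Pink noise matches
  the generic shape of EEG background spectra; no attempt is made to model
  alpha peaks or other structured rhythms.
* **Gamma bursts.** Gaussian-envelope bursts (default 40 Hz carrier, 20 ms
  envelope SD, 5 µV) at 90 and 280 ms after each light stimulus on occipital
  channels. With the default `random-per-trial` phase policy the carrier
  phase is redrawn each trial, so the bursts cancel from the trial average
  but persist in single-trial spectra — the defining property of
  non-phase-locked activity. The `locked` policy reuses one phase, moving
  the same power into the phase-locked branch; the pair of policies gives
  the dissociation experiment its positive and negative control.
* **Transducer artifact.** Broadband noise multiplied by the pulse-train
  envelope (1 ms on / 1 ms off at 500 Hz for 300 ms) on TUS trials, with
  amplitude `A·exp(−c·d)` in electrode–transducer distance `d` (defaults
  A = 20 µV, c = 0.3 cm⁻¹). The exponential law is a modeling choice — the
  phantom observation constrains only that the artifact decays with
  distance — and the phantom configuration (evoked and gamma amplitudes
  zero) reproduces an artifact-only recording whose spectral content is
  confined to the 300 ms sonication window.
* **Blinks.** Optional slow 150 µV frontal deflections at a configurable
  per-trial rate, used to exercise amplitude rejection.

What the generator does **not** emulate: realistic head geometry or lead
fields, structured ongoing rhythms, non-stationary noise, electrode drift
or failure, anesthesia-depth latency shifts, and any biophysics of the
ultrasound–neuron interaction. Passing tests therefore demonstrate that the
analysis recovers effects *of the assumed form* at realistic SNR — not that
the pipeline is robust to everything real recordings contain.

## Preprocessing

The order is fixed: band-pass → epoch → amplitude rejection → trial
equalization → (TUS conditions only) ICA cleaning.

* The 2–50 Hz band-pass is realized as a 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`); zero phase preserves the component
  latencies the N70/P100 windows depend on.
* Epochs span [−200, 800) ms — 1000 samples at 1000 Hz with t = 0 at the
  onset sample (0-based indexing, closed-open window). Events without
  enough pre/post context are skipped with a warning rather than aborting.
* Amplitude rejection flags trials exceeding ±100 µV (configurable) on any
  channel. Rejection only updates the acceptance mask; voltages are never
  mutated.
* Equalization keeps the chronologically first 250 accepted trials per
  block × condition cell. A deterministic "first n" rule avoids hidden
  randomness; cells with fewer trials keep all of them and warn.
* ICA (FastICA, seeded) runs on TUS-containing conditions only, mirroring
  the scope of artifact removal in the source experiment (light-only trials
  cannot contain a transducer artifact). Component rejection is fully
  automated with four scores per component: the 20–40 Hz band-power ratio
  (muscle-band excess), the coefficient of variation of 1 s-window power
  (burstiness), a spatial-concentration index (max |mixing weight| / sum) —
  a numeric surrogate for the "clustered topography" criterion, since no
  electrode geometry is modeled — and an evoked-similarity protection: a
  component whose trial-averaged time course correlates with the grand
  evoked response above |r| = 0.6 is never removed. Default thresholds
  (band ratio 0.5, CV 1.0, concentration 0.8) are exposed in the config.
  Where a supervised analyst would adjudicate borderline components, these
  thresholds decide; they were chosen on constructed mixtures with labeled
  artifact sources.

## VEP quantification

N70 is the minimum voltage in 60–100 ms, P100 the maximum in 90–130 ms, per
electrode, on the trial-averaged response of accepted trials; ties resolve
to the earliest latency. Peak-to-peak is P100 − N70; the electrode mean is
taken *after* per-electrode peak detection and normalization divides by the
same animal's baseline-block electrode mean (average-then-normalize). The
wording of the original procedure is ambiguous between
average-then-normalize and normalize-then-average; the former is the
default and the latter is available via `per_electrode=True`. The 15-point
moving average seen in published evoked traces is display-only and lives in
a separate plotting utility, never in the quantification path. The
laterality index is `100·(1 − mean p2p(ipsilateral occipital) / mean
p2p(contralateral occipital))`.

## Spectral decomposition

Complex Morlet wavelets, 50 center frequencies spanning 2–55 Hz with cycle
counts increasing linearly from 3 to 10 across the family; the temporal SD
of each wavelet is `cycles/(2πf)` and wavelets are unit-energy normalized.
Frequency spacing is linear by default (the source range admits either
reading; `spacing="log"` is available). Convolution is computed in the
frequency domain after reflection-padding each trace by one wavelet
half-support (±4 SD of the widest wavelet), and the result is sampled back
on the epoch time axis — reflection padding keeps edge artifacts out of the
baseline window.

Total power averages per-trial squared magnitudes (then the selected
channels). NPL power applies the same decomposition after subtracting the
per-channel trial-average from every trial; PL is the elementwise
difference total − NPL, which by linearity of the transform equals the
power of the trial-averaged signal and is non-negative up to rounding.
Negative PL residue is clipped at zero before dB conversion (the clip count
is logged). dB maps are `10·log₁₀(power / per-frequency mean over
−150..0 ms)`; baselining requires strictly positive baseline power and is
refused twice.

## Permutation statistics

The observed statistic is the difference of the two conditions' baselined
mean spectrograms. The null shuffles trial-to-condition assignments,
recomputing the dB difference per permutation (1000 by default; fewer than
100 is refused as too unstable in the tail). Two-sided p-values use the
add-one convention `(1 + #{|null| ≥ |obs|})/(n_perm + 1)`, and the p < 0.05
mask is uncorrected by default, with an optional cluster-size correction
behind a flag. Trials — not animals — are the permutation unit; that is an
assumption, stated here because the source analysis does not specify it.
The null pool is ordered by a content hash of each trial before
permutation, which makes the null depend only on the pooled trial multiset:
at a fixed seed, swapping the two condition labels negates the difference
map and leaves the p-map exactly unchanged for equal group sizes (and
distributionally otherwise). Per-trial power stacks may be decimated along
time (default ×4 in the pipeline) to bound memory; p-values are computed on
the decimated grid.

Degenerate t-test inputs follow explicit conventions: all-zero paired
differences give t = 0, p = 0.5 (one-sided); equal nonzero differences give
t = ±∞ with p at the corresponding bound. Dose-response reports both
Pearson and Spearman coefficients, since the functional form of the
displacement–suppression coupling is unknown; constant input is an error
rather than a NaN.

## MR-ARFI

`D = ΔΦ/(2γGτ)` per voxel, with the phase difference computed through
complex exponentials (`angle(exp(iΔφ))`) so wrap-around at ±π cannot
corrupt it. γ is fixed to the proton value (γ/2π = 42.58 MHz/T) unless
overridden; G defaults to 0.04 T/m; τ has **no default** — displacement in
meters is meaningless without the actual lobe duration, so construction
fails loudly if it is missing (3 ms is used as the example value
throughout the simulations). The focal maximum is the largest absolute
displacement in an ROI; it is declared "not detectable" unless it exceeds
k = 3 times the background noise SD (estimated robustly from outside the
ROI when not supplied) — an operationalization of excluding a subject whose
focal spot cannot be distinguished from noise.

## Dose and bioheat

Duty cycles: within-train = pulse/PRI (0.5 for 1 ms/2 ms), train =
300 ms/1 s = 0.3, total = 0.15; `I_SPTA = I_SPPA × total`. The plane-wave
relation `I = p²/(2ρc)` is provided as a utility, but pressures and
intensities are treated as independent inputs: published pressure and
intensity ranges for this protocol are not mutually consistent under the
plane-wave relation with standard tissue constants (they derive from
hydrophone calibrations that cannot be reconstructed), so the package never
converts one into the other implicitly.

The bioheat solver integrates `ρC ∂T/∂t = k∇²T − w_b ρ_b C_b (T − T_a) + Q`
with an explicit scheme on a regular 1/2/3-D grid. The Laplacian is
assembled from face fluxes with zero flux at the boundary, so with no
source and no perfusion the total heat content is conserved to rounding
error — this, together with the uniform-source steady state
`ΔT = Q/(w_b ρ_b C_b)` and the analytic spreading of a Gaussian under the
heat kernel, forms the solver's validation set. The stability bound
`dt ≤ ρC/(2kΣ1/dxᵢ² + w_b ρ_b C_b)` is checked and reported on violation;
the default step is 90% of the bound. Tissue constants default to generic
brain/blood values (k = 0.52 W/m/K, ρ = 1046 kg/m³, C = 3630 J/kg/K,
ρ_b = 1050 kg/m³, C_b = 3617 J/kg/K) and are meant to be overridden when a
specific tissue table is available. The heat source from intensity is
`Q = 2αI`, time-averaged over the total duty cycle by default with a
pulsed-source toggle. Simulated heating through real skulls is explicitly
not a validation target — that requires transcranial acoustic propagation
(and CT skull models), which is out of scope; the solver is validated
against closed forms instead.

## Pipeline

`run_study` derives each LGN-group experiment's suppression from its focal
displacement via `s = 1 − c·d/d_ref` (defaults c = 0.5, d_ref = 2 µm),
making the dose-response coupling explicit and configurable; sham
experiments keep s = 1 with a small off-target displacement — an
intentional version of a sham that in practice arises from transducer
dislocation. Light-only trials within sonication blocks are the default
VEP substrate (they cannot contain stimulation artifacts); light+TUS
quantification is available for immediate-effect comparisons. The manifest
records a config hash and per-output checksums; HDF5 outputs are hashed
over their logical dataset contents, since the container format embeds
write times. Deterministic stages are checksum-stable across reruns at a
fixed seed.

## Problem sizes

The default test and acceptance runs use scaled schedules chosen to keep
the suite quick while preserving the quantities of interest: suppression
recovery uses the full 250-trial condition (5 baseline minutes + 18
sonication sections); the dissociation maps use 120 trials; the permutation
calibration uses 200 trials per condition and 1000 permutations over a
×4-decimated time axis (12 500 pixels); the end-to-end pipeline tests use
2-section blocks and 25 trials per cell.

## Known limitations

* The generator's artifact and noise models are simple; ICA thresholds
  calibrated on them may need retuning for real recordings.
* Laterality uses a fixed ipsi/contra electrode split from the montage
  metadata; no electrode-failure handling beyond erroring when a side is
  missing.
* The permutation unit is the trial; animal-level resampling is not
  implemented.
* No transcranial acoustic propagation: acoustic intensity at the focus is
  an input everywhere, never derived from transducer drive or skull
  properties.
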