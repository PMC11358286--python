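# Methods

`synchrolab` analyzes paced finger tapping to perturbed metronomes and the
EEG connectivity that accompanies it. This note documents the models and
procedures the package implements, the parameters that matter, the
synthetic-data generator used for validation, and the design choices made
where the design was genuinely open.

## Stimulus model

Metronome clicks are generated at a baseline rate of 0.8 Hz
(inter-stimulus interval, ISI, 1250 ms). Perturbed sequences modulate the
onsets in a period-4 early/late pattern: with modulation depth *m* and
Δ = *m*·ISI, the k-th onset is

    onset_k = k·ISI − Δ·sin(πk/2),

rounded half-to-even to integer milliseconds. Even-index onsets are
unperturbed; odd-index onsets alternate early and late. This is the unique
period-4 sinusoidal assignment consistent with the worked 3% example
(onsets 0, 1212, 2500, 3788, 5000 ms; rounding of the half-millisecond
deviations 1212.5→1212 and 3787.5→3788 fixes the half-to-even rule). The
modulation is mean-preserving: over every whole 4-onset cycle the mean
interval equals the ISI and the odd-index deviations cancel.

Depths ≥ 0.5 are rejected (adjacent onsets could collide). The 2000 Hz
start/end marker beeps of the paradigm are carried as metadata only; no
audio is synthesized. Whether deviations should be rounded to an audio
sample grid instead of integer milliseconds cannot be decided from the
printed example; integer milliseconds is the simpler convention and is
used throughout.

## Tap-train cleaning and synchronization measures

Cleaning applies three rules in a fixed order:

1. **Warm-up discard** — the first 10 taps of each run (initial tempo
   adjustment).
2. **Double-tap removal** — when two taps fall within 100 ms, the later
   one is excluded; scanning continues from the retained tap.
3. **ITI-outlier removal** — a tap whose preceding inter-tap interval is
   more than 50% shorter or longer than the baseline ISI is excluded. The
   target is the baseline ISI, not the locally modulated interval (even at
   20% modulation the modulated intervals stay inside the ±50% band, so
   the two choices coincide for the in-design conditions).

Double taps are removed before the interval rule because a spurious extra
tap corrupts the intervals on both sides of it. Within the interval rule,
a too-short exclusion keeps the last *retained* tap as the reference (so a
burst of rapid taps cannot ride in on its own shortened intervals), while
a too-long exclusion re-anchors the reference on the excluded tap. The
re-anchoring matters: if the reference never advanced past a long gap,
every subsequent interval measured from the pre-gap tap would also exceed
the band and the rest of the train would be discarded wholesale. A long
gap indicates missed taps, not defective later taps.

Each retained tap is then matched to its nearest click, with the signed
offset tap − click restricted to (−ISI/2, +ISI/2] — half-open, so a tap
exactly midway pairs with the earlier click. At most one tap per click;
the nearest wins, the earlier tap on an exact tie; losers are reported
unmatched.

Per run, four measures are computed: mean and SD of the inter-tap interval
(tapping rate and consistency) and mean and SD of the synchronization
error SE = tap − click (accuracy and variability; negative mean SE is the
negative mean asynchrony typical of anticipatory tapping). SE is reported
in milliseconds; "relative phase" is interpreted as this signed offset,
not a normalized angle — the magnitudes of interest live on the tens-to-
hundreds-of-ms scale. SDs are sample SDs (ddof = 1). The two runs of a
condition are averaged statistic-by-statistic (SD computed within run,
then averaged); an early-terminated session contributes its single run
unchanged.

Verbal reports (did the rhythm fluctuate?) are coded per condition:
correct only if every available run's answer is accurate (both runs
normally; the single run after an early termination).

## Adaptive staircase

Perceptual thresholds use a transformed 2-up-1-down staircase over 43
trials: one error raises the stimulus deviation by one step (easier), two
successive correct responses lower it (harder); the consecutive-correct
counter resets on every level change and every error. Asymptotically the
procedure concentrates at the level answered correctly with probability
1/√2 ≈ 70.7%. Start level, step, floor and ceiling are configuration
(defaults 40, 4, 0, 80 on the deviation-unit scale of child rhythm
thresholds — start ≈ 2× a typical threshold, step 10% of start); the
threshold estimate is the mean level at the last 6 reversals, the standard
short-track estimator. Clamped non-moves at the floor or ceiling record no
reversal.

Simulated observers use a logistic psychometric function
p(x) = γ + (1 − γ − λ)/(1 + e^(−β(x−θ))) with guess rate γ, lapse rate λ,
slope β and midpoint θ; higher deviations are easier, so β ≥ 0. The tests
verify, against a brute-force Markov-chain computation on the discrete
level grid (states = level × consecutive-correct count), that the visited
levels concentrate at the observer's 70.7%-correct level. Duration- and
rhythm-discrimination tasks share this engine and differ only in the
semantics of the deviation unit; stimulus audio is out of scope.

## EEG coherence

Continuous preprocessed EEG (250 Hz, 32-channel 10–20 montage,
average-referenced and artifact-cleaned upstream; the preprocessing stage
is a pluggable "cleaned EEG in" interface, not re-implemented) is epoched
around tap onsets: extended cuts −500..+500 ms are made, the per-channel
mean over −500..−300 ms (pre-movement baseline) is subtracted, and epochs
are cropped to −100..+500 ms — 600 ms, exactly 150 samples at 250 Hz. The
baseline window lies outside the analysis window, which is why the
extended-cut-then-crop order is required. Rest recordings (30 s) are cut
into consecutive non-overlapping 600 ms epochs with no baseline step.

For each channel pair, coherence is

    C_xy = |E[S_xy]| / √(E[S_xx]·E[S_yy]),

with time-resolved spectra from complex Morlet wavelets (one cycle) at
center frequencies 12, 14, …, 30 Hz (equal-weight 2 Hz grid across the
beta band; the grid spacing is a free choice). Wavelet kernels come from
`mne.time_frequency.morlet`; time samples whose kernel support overhangs
the epoch edge are excluded from the expectation (the longest kernel, at
12 Hz, still fits well inside the 600 ms epoch). Two granularities are
computed and labeled: per-epoch coherence (expectation over time and band
within one epoch — the samples the distributional test needs) and
across-epoch coherence (expectation jointly over epochs, time and band).
C_xy is symmetric, lies in [0, 1], equals 1 for identical or rescaled
channels, and is invariant to per-channel amplitude scaling; a zero-power
channel makes its links undefined (NaN, flagged).

Per link, the task-minus-rest difference of mean per-epoch coherence is
retained only where a two-sample Kolmogorov–Smirnov test across epochs
rejects equality of the task and rest distributions at p < 0.01
(unadjusted); otherwise the difference is set to zero. Links zeroed for
having fewer than 5 epochs are flagged separately from genuine
non-significant zeros. Masking is applied after band averaging. Channels
PO7, PO3, PO4, PO8 and Oz are excluded from connectivity. Masked
differences are averaged within three fronto-central link groups —
intrahemispheric contralateral (Fp1–F3, F3–C5, C5–C1), midline (Fz–Cz,
Fz–Pz), interhemispheric (Fp1–Fp2, F3–F4, C5–C6) — and then element-wise
across participants within a group for the matrix-style difference
tables.

## Synthetic cohort generator

The generator exists so every stage is testable end to end without human
data. It emulates three groups — children with developmental coordination
disorder (DCD, n = 9), typically developing children (TD, n = 11) and
typically developing musicians (TDM, n = 12) — under the study design
(four conditions × two runs × 60 stimuli).

**Tapping.** The tapper is the standard linear phase-correction process:
with asynchrony A_n = tap_n − click_n, correction gain α ∈ (0, 1],
preferred asynchrony *nma* (negative = anticipatory), timekeeper noise T_n
and motor noise M_n,

    tap_{n+1} = tap_n + ISI − α(A_n − nma) + T_n + M_{n+1} − M_n.

Stimulus-onset deviations enter through the click times, so perturbed
conditions inflate asynchrony variability naturally. The stationary
asynchrony variance has the closed form
σ²_T/(1−β²) + 2σ²_M/(1+β) with β = 1−α, used to calibrate the timekeeper
noise so each group × condition preset hits its target mean asynchrony
and SD (targets on the scale of child tapping studies, e.g. DCD
isochronous: −117/183 ms; TDM isochronous: −51/86 ms; all groups at 20%
modulation: asynchrony near zero with SD ≈ 240–320 ms, the reactive
regime). Defaults α = 0.5, motor SD 10 ms. A configurable double-tap rate
(default 0.02/tap, extra tap 20–80 ms later) exercises the cleaning rule.
The generator starts at the stationary distribution, so recovery of the
planted mean and SD through the full cleaning-and-matching pipeline is a
direct acceptance check (±5 ms and ±10% at 10⁴ taps).

**Verbal reports.** Per-run report probabilities per group × condition
(near-ceiling at 20% modulation, near-floor at 3%, intermediate at 7%,
group-dependent false alarms on the isochronous sequence) reproduce the
qualitative accuracy pattern of conscious detection: only the large
perturbation is reliably detected.

**EEG.** Each channel carries independent 1/f background noise (SD
10 µV); every network link mixes a shared beta-band (12–30 Hz) source
into its two channels with weight coupling × 10 µV, amplitude-modulated
by Gaussian bumps (SD 100 ms) jittered around tap times during the task.
Rest recordings use a uniform baseline coupling of 0.3. Task presets:
DCD — all networks at rest coupling in both contrast conditions (no
task-dependent reorganization); TD — interhemispheric raised to 1.0 at
20% modulation only; TDM — interhemispheric 0.8 at isochronous and 1.2 at
20%. Estimated coherence is monotone in the planted coupling, and equal
task/rest couplings yield masked differences ≈ 0 (the KS mask passes
≈ the α fraction). Because network channels are shared between links,
strong coupling on one network leaks mild extra beta power into
neighboring links — a realistic imperfection the mask handles.

The generator does **not** model volume conduction, dipole geometry,
developmental age effects or comorbidity; passing tests show the pipeline
recovers planted structure of the assumed form, not that real pediatric
EEG satisfies these assumptions.

All randomness flows from one cohort seed through
`numpy.random.SeedSequence.spawn`, one child per participant in a fixed
order; identical seeds give byte-identical datasets. By default on-disk
EEG is written (as EDF, int16) for the isochronous and 20% conditions —
the contrast analyzed downstream — while tapping and verbal responses
cover all four conditions; full-EEG generation is a flag. The in-package
EDF writer exists because the environment provides EDF reading but not
writing; round-trips through `mne.io.read_raw_edf` are tested (max
quantization error ~1e-4 of the channel range).

## Pipeline and problem sizes

`report.run_pipeline` consumes a dataset directory (tap log, response
log, onset files, optional EEG), produces participant summaries, the
group synchronization table, the verbal-response table, per-link and
per-network coherence tables, matrix-style difference plots and a
manifest with input hashes. EEG epochs are locked to *cleaned* taps and
the runs of a condition are pooled before coherence and masking (two
60-stimulus runs minus warm-up ≈ 100 epochs per condition). Inferential
statistics (mixed ANOVA with sphericity correction, effect sizes) are
delegated to pingouin behind one function and labeled as such.

Default validation sizes: the end-to-end cohort run uses the full 9/11/12
groups with network-link coherence (≈ 15 s); the coherence oracle check
uses 4 channels × 50 epochs; staircase convergence uses 1000 tracks of 43
trials plus 20 long (2000-trial) tracks against the Markov chain; tapper
recovery uses 10⁴ taps per preset; the KS-mask null calibration uses 500
links × 50 epochs. Percentages in output tables are rounded to one
decimal.

## Known limitations

- The coherence estimator assumes equal epoch lengths and a common
  sampling rate; resampling is out of scope.
- The per-epoch/across-epoch split follows the definition above; if an
  upstream implementation used single-taper Fourier per epoch instead of
  the same Morlet kernels, per-epoch values would differ in detail while
  the across-epoch estimator and masking logic are unchanged.
- Tap-to-click matching is greedy per click rather than a global optimal
  assignment; with cleaning applied first, conflicts are rare.
- The synthetic EEG's "networks" are constructed directly on the named
  electrode pairs; no claim is made about sources or anatomy.
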