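# Methods

This note documents the models, generator assumptions, numerical choices and
limitations of the package. Units are seconds, Hz and microvolts throughout.

## Experiment design

The plan generator crosses SNR (0, −10 dB) × memory load (1-, 2-back) ×
distractor predictability into 16 blocks of 120 target/distractor pairs
(onset-to-onset 2 s). The numbers 1–8 are randomly split into two groups of
four; the two repeats of each condition cell swap the groups' target/distractor
roles, and one repeat is attend-left, the other attend-right (randomised per
cell), so exactly half the blocks are attend-left. Block order is a seeded
uniform permutation; no further block-order constraint is imposed because none
is part of the design.

**n-back events.** "20% of the presented numbers" is implemented as 20% of
the *scoreable* positions (trial index > n), rounded to the nearest integer —
24 events for both 1-back (119 scoreable) and 2-back (118 scoreable) blocks.
Events are a uniform random subset of the scoreable positions. The sequence is
then built constructively: event positions copy the item n back; every other
position draws uniformly from the numbers that do **not** match at lag n. This
gives the exact event census, guarantees no unintended matches at the task
lag, and needs no rejection sampling. Accidental matches at the *other* lag
(e.g. 2-back repeats inside a 1-back block) are permitted: only the
task-relevant lag defines an event.

**Distractor streams.** Predictable blocks cycle a random permutation of the
four distractor numbers (transition probability 1). Unpredictable blocks draw
each item uniformly from the numbers differing from the previous and
penultimate item: p = 1/3 per alternative at position 2, p = 1/2 from position
3 on. `empirical_transition_stats` estimates the conditional next-item
frequencies that validate this structure.

## Signal-detection behaviour

Simulated presses follow an equal-variance Gaussian SDT model per condition
cell: P(press | target) = Φ(d′/2 − c), P(press | non-target) = Φ(−d′/2 − c),
reaction times uniform in (0, 2]. Default generator values — d′ = 3.0
(1-back) / 2.2 (2-back); c = 0.40, +0.25 under 2-back, and 0.25 in the easiest
cell (0 dB, 1-back, predictable) — encode high sensitivity, a conservative
bias that deepens with memory load, and a less conservative bias when the task
is easiest with a predictable distractor. The analysis inverts this model:
hits and false alarms are pooled over the two blocks of a cell, extreme rates
0 and 1 map to 1/(2N) and 1 − 1/(2N) with N the relevant trial count (target
count for hit rate, non-target count for false-alarm rate), then
d′ = z(H) − z(FA) and c = −(z(H) + z(FA))/2 (positive = conservative).

## Synthetic EEG

Each epoch (−1…1 s, default 250 Hz; the analysis windows are specified in
seconds, so results are sampling-rate invariant) is a sum of three parts. A
uniform 10-10 geometry from the bundled MNE template supplies electrode
positions for all spatial weighting; no volume-conduction model is implied.

1. **1/f background** — Gaussian noise spectrally shaped to f^(−1), calibrated
   to 9 µV broadband SD per channel, independent across channels and trials.
2. **Lateralised alpha** — one 10-Hz oscillator per hemisphere with random
   phase per trial, log-normal amplitude jitter (σ = 0.2, shared by both
   hemispheres so it cancels in power ratios), and a Gaussian scalp profile
   (σ = 9 cm) centred on PO3/PO4 restricted to the oscillator's own
   hemisphere's channels — the restriction makes per-channel and pooled power
   ratios equal the configured index exactly. The hemispheric amplitude gains
   are g_ipsi = √(1+a(t)), g_contra = √(1−a(t)), so the power index
   (P_ipsi−P_contra)/(P_ipsi+P_contra) of the oscillation equals a(t). The
   target profile a(t) has plateaus over the configured windows **extended by
   0.25 s** (half the spectral-analysis window) on each side with 80-ms
   raised-cosine ramps, so every moving-window power estimate centred inside a
   window sees the full plateau. Defaults: a = −0.1 in T1 (−0.5…−0.35 s) for
   unpredictable distractors only, a = +0.2 in T2 (0.3…0.5 s) for all
   conditions; per-subject window offsets are N(0, 0.05). The alpha amplitude
   (14 µV at the profile centre) keeps the in-band alpha-to-noise power ratio
   around ten, so the ratio index is attenuated by well under 10% by the noise
   floor.
3. **Evoked components** — Gaussian pulses P1 (+2 µV, 50 ms, Cz), N1 (−4 µV,
   100 ms, FCz), P2 (185 ms, σ = 22 ms, FCz) and a ramped-boxcar frontal
   negativity (0.4–0.8 s, Fz), each with a Gaussian scalp profile (σ = 6 cm).
   Condition effects are additive amplitude deltas matching the study's
   direction of effects: P2 = 3.0 µV baseline, +0.5 for 0 dB SNR, +0.2 for
   2-back, +0.4 for unpredictable distractors, −0.3 on n-back targets;
   frontal negativity = −1.5 µV baseline, −0.4 for 0 dB SNR, −0.5 for 1-back,
   −0.3 for predictable distractors under 1-back and +0.2 under 2-back (the
   load-dependent predictability effect). Per-subject component offsets are
   N(0, 1.5 µV), giving the mixed models a genuine participant intercept.

What the generator does **not** emulate: ocular/muscle artefacts (hence no
ICA stage), volume conduction and correlated sensor noise, alpha with
realistic 1/f-embedded bandwidth (the oscillator is a pure sinusoid),
latency jitter of evoked components, and reaction-time structure. Passing
recovery tests therefore demonstrate the correctness of the analysis chain
under the stated statistical structure, not robustness to artefacts of real
recordings.

## Preprocessing

Zero-phase two-pass Butterworth band-pass (0.1–100 Hz, order 8, giving > 20 dB
two-pass attenuation at 120 Hz with a flat pass band). Filtering uses maximal
`filtfilt` padding: the 0.1-Hz pole settles slowly relative to a 2-s epoch and
scipy's default pad length leaves visible startup transients. Trials whose
absolute amplitude exceeds 160 µV anywhere are flagged (strict inequality;
metadata travels with the data through every selection). Re-referencing is
common-average or linked-mastoid (TP9/TP10); baseline correction subtracts the
−0.2–0 s mean. Block-initial trials (first of 1-back, first two of 2-back
blocks) are excluded from behaviour and EEG alike. Baseline correction and
re-referencing are both linear and commute (verified numerically). ICA-based
artefact removal is intentionally absent — it requires visual component
selection and the synthetic data contain no such artefacts; an optional
deterministic flat/high-variance channel detector with nearest-neighbour
averaging stands in for visual bad-channel interpolation.

## ERP analysis

Epochs are mastoid-referenced and baseline-corrected; condition averages use
retained trials only. The P2 window is found from the grand average across
all conditions and subjects: the positive peak between 0.1 and 0.3 s over
midline candidates (Fz/FCz/Cz), snapped to the sample grid, ± 25 ms, with the
peak electrode and its two same-row neighbours (FC1/FCz/FC2 for a
fronto-central peak). The frontal negativity uses the fixed 0.4–0.8 s window
at F1/Fz/F2. Single-trial amplitudes (mean over the window's samples and
electrodes) are modelled as

    amplitude ~ SNR * load * predictability + (1 | participant)

with centred effect coding (−0.5/+0.5; +0.5 = 0 dB, 2-back, unpredictable),
so each "main effect" is marginal across the other factors and its
coefficient equals the injected amplitude delta. Attend-left and attend-right
trials are pooled (the model has no side term). Sub-group refits (per load
level) and the target-vs-non-target contrast reuse the same machinery with a
different factor set.

The mixed model is a random-intercept LMM fit by profiled REML: with
V_j = σ²(I + λ11′) per participant, the criterion reduces to per-group
sufficient statistics and a 1-D optimisation over log λ (bounded, with the
λ = 0 boundary checked explicitly and reported as a singular fit).
Satterthwaite df follow df = 2f²/(gᵀ A g) with f the coefficient's sampling
variance as a function of θ = (τ², σ²), g its central-difference gradient
(relative step 1e-5), and A = 2H⁻¹ the inverse observed REML information from
a central-difference Hessian. Estimates agree with statsmodels MixedLM and
the df with lmerTest's Satterthwaite values to better than 1e-3 relative
(frozen oracle in the test suite). Effect sizes are r = √(t²/(t²+df)).

## Time-frequency analysis and lateralisation indices

Power comes from a moving-window FFT: 500-ms Hanning taper, zero-padded to
1 s to evaluate a 1-Hz grid (1–50 Hz) at −0.7…0.7 s in 50-ms steps. The
padding interpolates between the window's native 2-Hz bins; the interpolated
bins carry leakage of neighbouring native bins, which cancels in power
ratios. Power is scaled so a sinusoid of amplitude A yields its mean-square
power A²/2. Time points whose window would leave the epoch raise an error
rather than being padded. Inner products run in single precision by default
(ample for physiological dynamic range; a double-precision switch exists for
numerical studies — the noise-free lateralisation oracle agrees with the
closed form to ~1e-5, limited by positive/negative-frequency interference of
the finite taper, not precision).

Power is averaged over trials within attend-side/condition, and over the
8–12 Hz band and ROI electrodes, **before** any index is formed: AMI and ALI
are ratios of averaged power, not averages of ratios. The posterior ROI is
the 12 left/right pairs TP9/10, TP7/8, CP5/6, CP3/4, CP1/2, P7/8, P5/6, P3/4,
P1/2, PO7/8, PO3/4, O1/2 (TP9 is retained despite having served as online
reference: after average re-referencing it carries signal). Window selection
runs a paired t-test of left- vs right-hemisphere ROI AMI at every time
point, Benjamini–Hochberg FDR across time points, and returns maximal
contiguous significant runs; the defaults T1 = −0.5…−0.35 s and
T2 = 0.3…0.5 s are the windows this procedure selects under the default
generator. Window-averaged ALI per condition (the two attend-sides of a cell
averaged) enters a 2 (SNR) × 2 (load) × 2 (window) × 2 (predictability)
within-subject ANOVA with per-window follow-ups.

## Shared statistics

The repeated-measures ANOVA is the standard univariate within-subject
decomposition (each effect against its own subject × effect interaction, via
statsmodels `AnovaRM`), with partial η² = F·df_num/(F·df_num + df_den). All
within factors are two-level, so sphericity holds trivially and no correction
is applied. Paired t-tests are two-sided with Cohen's d = |t|/√n. FDR is
Benjamini–Hochberg step-up (statsmodels), verified against a brute-force
implementation of the step-up definition.

## Seeding and problem sizes

One master seed drives a `numpy.random.SeedSequence`; per subject, child
sequences are spawned for the plan, the presses and the EEG, so subjects can
be processed in any order with bit-identical results. Simulation studies in
the test suite use deliberately scaled designs chosen for comfortable
statistical margins at desk scale: d′/criterion recovery uses 200 replicate
subjects on the full 1920-pair design; alpha-lateralisation recovery uses 33
subjects at full trial counts on the ROI channels; the lateralisation-ANOVA
power check uses 50 replicates of 6 subjects with 24 pairs per block; ERP
sign recovery uses 20 replicates of 8 subjects with 80 pairs per block; the
mixed-model null calibration uses 200 replicates of a direct amplitude-level
null generator; FDR window-selection behaviour uses 60 null and 15 effect
replicates of 5–6 subjects with 12–20 pairs per block.

## Known limitations

* The LMM supports a single random intercept (the only random-effects
  structure the analyses need); no random slopes.
* The average reference interacts mildly with the hemisphere-restricted alpha
  sources (the subtracted common signal redistributes a few percent of power);
  simulation studies that pick ROI channels only therefore skip the average
  reference, which is exact for the generator.
* EDF export of continuous data is not provided; epochs persist as HDF5 with
  TSV metadata.
* The moving-window FFT evaluates requested bins directly (matrix DFT) when
  few are needed and falls back to a full FFT otherwise; both paths share
  taper and scaling.
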