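# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of `strokebci`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic EEG model

Each channel of a session is the sum of three components, in microvolts:

1. **Lateralized oscillatory sources.** One source per hemisphere, located
   at C3 (left) and C4 (right), each emitting a mu (10 Hz, 6 µV) and a beta
   (22 Hz, 3 µV) sinusoid with a random phase per run. Source activity
   reaches every channel through a Gaussian spatial gain
   exp(−d²/2σ²) over planar 10–20 electrode distances, σ =
   `topography_width` = 0.35 head-radius units. This width puts ~50% of the
   source amplitude on the adjacent midline electrodes (Cz, CPz …) and ~7%
   on the opposite motor electrode — deliberate, realistic cross-channel
   leakage; note both hemispheric channel sets share the four midline
   electrodes, so a strong source is never fully invisible to the opposite
   set.
2. **Slow amplitude modulation.** Each (source, band) amplitude is
   multiplied by 1 + 0.2·z(t), z a unit-variance Gaussian process low-passed
   at 0.5 Hz (floored at 0.05). Real sensorimotor rhythms wax and wane over
   seconds; without this term every trial would carry an identical,
   deterministic oscillator power and across-trial feature variability
   would be unrealistically small.
3. **Noise.** A 1/f^α background (α = 1.0, 8 µV RMS — a typical resting-EEG
   spectral slope) synthesized by spectrally shaping white noise, plus 1 µV
   white sensor noise. The background's scale factor is computed
   *analytically* from the spectral shape rather than from the realized
   sample RMS: normalizing each run to its sample variance would constrain
   total run power and induce a negative correlation between trial powers,
   which measurably biases null cross-validation below chance.

**Event-related modulation.** During a motor-imagery trial the oscillator
amplitude over hemisphere *h* is multiplied by (1 − d_h) from 0.5 s after
the cue (the known ERD onset latency) to the end of the 4 s task window,
then by (1 + `ers_rebound`) for 1 s (ERS). Idle trials are unmodulated. An
amplitude scale of (1 − d) implies a band-power change of
100·((1 − d)² − 1) percent — the analytic ground truth used throughout the
tests (e.g. d = 0.5 → −75%).

**Protocol.** 4 runs × (20 MI + 20 idle) trials in per-run random order,
160 trials per session; cue-to-cue intervals jittered uniformly within
±1 s of the 12 s nominal trial; 250 Hz sampling; 27-channel 10–20 montage.
Random streams are split per (patient, run) from a seed sequence, so
generating a larger cohort never perturbs earlier patients, and identical
configurations are bit-identical.

**Cohort profiles.** `generate_cohort` draws lesion sides balanced,
Fugl-Meyer scores and months-since-stroke from the published clinical
distributions of screening cohorts (FMA 28.6 ± 12.9 overall; ~1/8 subacute
at 3.3 ± 1.5 months, the rest chronic at 23.7 ± 17.7), and ERD depths per
profile: `null` (0, 0), `balanced` (both ≈ U(0.35, 0.6) ± 0.05),
`contra_dominant` / `ipsi_dominant` (dominant side U(0.45, 0.65), other
U(0.05, 0.2)). Contra-dominant patients draw FMA from a lower range
(17 ± 9), encoding the observed association between contralesional
dominance and motor impairment. These ranges were fixed once, before the
cohort-level checks were run, to span chance-to-ceiling decodability.

## Decoding pipeline

- **Filtering.** 4th-order Butterworth band-pass applied forward–backward
  (`sosfiltfilt`, effective 8th order, odd-reflection padding): zero net
  group delay, so ERD timing is preserved. Applied per epoch, so the
  pipeline also accepts data delivered pre-epoched. 8–30 Hz for CSP and BP;
  nine 4 Hz bands (4–8 … 36–40 Hz) for FBCSP.
- **CSP.** Per-trial covariance XXᵀ normalized by its trace, averaged
  within class; generalized eigenproblem C₁w = λ(C₁+C₂)w with a 1e−8·I
  ridge on the composite for rank safety. Rows sorted by descending λ,
  signs fixed so the largest-magnitude weight is positive (backend
  independence). Features: log(v_k/Σv) over the first/last `n_pairs`
  filters — invariant to global trial rescaling, Σexp = 1.
- **BP.** The literal log of 100·(T−B)/B is undefined whenever ERD occurs
  (T < B), so the default feature is the odd, everywhere-defined signed log
  sign(r)·ln(1+|r|), which tracks ln(r) for large positive r; the literal
  form is available behind `strict=True` and raises on r ≤ 0.
- **MIBIF / NBPW.** One shared density machinery: per-(class, feature)
  Gaussian Parzen estimates with Silverman bandwidth σ̂·(4/3n)^{1/5},
  floored at 1e−6 of the feature's global scale to survive degenerate
  spreads. MI is H(class) − H(class|feature) in bits, the conditional term
  a sample average of posterior entropies, clipped at 0. MIBIF keeps the
  plain top 4 (ties to the lower index); CSP's 4 features skip selection.
  Pair-completion of CSP feature pairs is deliberately not the default.
  NBPW multiplies per-feature likelihoods in log space; exact posterior
  ties resolve to idle.
- **Cross-validation.** 10 runs × stratified 10-fold; fold seeds split from
  a master seed. Filtering and per-trial BP features are precomputed (no
  cross-trial fitting); CSP/FBCSP fitting, MIBIF and NBPW are refit per
  fold on training trials only. Accuracy is the per-fold percent correct
  averaged over all 100 folds, not a pooled confusion matrix.
- **Statistics.** Wilcoxon signed-rank (zeros dropped, tie-averaged ranks;
  exact null for n ≤ 25 untied, else continuity-corrected normal), Kendall
  tau-b (exact for n ≤ 8 untied), Mann–Whitney for the between-strata
  Fugl-Meyer comparison (the non-parametric choice consistent with the
  rest), no multiple-testing correction (α = 0.05 throughout). Chance
  threshold: smallest k with BinomialCDF(k; n, ½) ≥ 0.99, as a percentage —
  59.375% at n = 160. Strata are strict: accuracy < 60% and > 80%;
  boundary values belong to neither.

## ERD/ERS mapping

Time–frequency maps use 1 s Hann-tapered periodograms stepped by 0.1 s
(≥1 Hz resolution over 4–40 Hz with smooth time courses); each frequency
row is referenced to its mean over the sliding windows fully inside the
1.5 s pre-cue baseline, making baseline columns average to zero by
construction. ERD/ERS curves band-pass 8–30 Hz, square, trial-average,
smooth with a 0.25 s moving average, and reference the same baseline. Both
are invariant to positive rescaling of the raw data, so per-patient maps at
the lesion-resolved C3/C4 electrode can be averaged element-wise into grand
averages.

## Problem sizes and calibration findings

The cohort-level checks run the full pipeline at desk scale: 50 null
patients and 20-patient lateralized cohorts in the test suite; 30 and 12 in
the acceptance script. The CSP pipeline is used for cohort sweeps — it is
the cheapest of the three and directly captures the broadband variance
change the generator encodes.

Two empirical findings are worth recording:

- **Null cross-validation is conservatively biased.** With the protocol's
  exact within-run class balance (20+20), each trial's label is negatively
  correlated with the remaining labels; spatial filters overfit to random
  trial-power differences therefore become *anti*-predictive out of fold,
  and the null-cohort accuracy distribution centres a few points below 50%
  (an iid-trials control recovers ~50%, confirming the pipeline itself is
  unbiased). The bias is conservative — it cannot manufacture spurious
  above-chance performance — and the chance-threshold exceedance rate stays
  at the nominal ~1%.
- **CSP does not dominate the peak electrode here.** Because the simulated
  source gain peaks exactly at C3/C4, the single peak channel is already a
  near-optimal spatial filter, and with amplitude-modulated sources the
  trial-to-trial power spread grows with the source fraction, so the top
  CSP feature's standardized mean difference does not exceed the best
  single-channel variance feature on generator data. CSP's multi-channel
  advantage is real and is verified on data whose source is mixed evenly
  across channels.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: lateralized
band-limited ERD/ERS with controllable depth per hemisphere, realistic
spatial leakage, 1/f background, balanced trial design, clinical covariate
distributions and their association with effect laterality. It does not
simulate volume-conduction forward models, eye/muscle artifacts (the
analysis pipeline likewise applies no artifact rejection), electrode drift,
non-sinusoidal rhythm shape, or session-to-session nonstationarity. Passing
tests therefore certify the correctness and calibration of the *analysis*,
not the difficulty of real clinical EEG: absolute synthetic accuracies are
optimistic, and real cohort accuracy tables are not expected to be
reproduced numerically.

## Known limitations

- EDF+ export requires mne's optional `edfio` backend; without it,
  persistence falls back to CSV/HDF5 (reading EDF needs only `mne`).
- The NBPW prediction cost grows linearly with training-set size (kernel
  sums are not truncated or tree-accelerated) — irrelevant at 160 trials.
- `stratify_and_compare` skips (with an explicit note) comparisons whose
  stratum has fewer than 5 usable pairs, the minimum for the signed-rank
  test.
- Re-referencing/montage harmonization across amplifiers is out of scope;
  recordings are consumed as given.
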