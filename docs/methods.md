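# Methods

`eegscreen` implements a complete case–control screening analysis for
resting-state EEG: preprocessing with automated artifact handling, a fixed
1,046-dimensional feature space, propensity-matched weighted regression
screening with family-wise correction, nested leave-one-out classification,
and per-sex univariate ROC thresholding. Because studies of this design
typically cannot share raw clinical EEG, the package ships a synthetic
cohort generator with known ground truth; every statistical guarantee the
pipeline makes is validated against that generator or against brute-force
oracles.

## Recording model and preprocessing

Recordings are 19-channel international 10–20 montages (Fp1 … O2, legacy
temporal naming; modern T7/T8/P7/P8 labels are accepted as aliases) sampled
at 256 Hz in microvolts, nominally referenced to A1. The preprocessing
chain is fixed, in order:

1. **50 Hz notch** (zero-phase FIR, 2 Hz stop band),
2. **0.5–42 Hz bandpass** (zero-phase FIR, Hamming design),
3. **average reference** (instantaneous mean over channels subtracted),
4. **bad-channel removal**, by three criteria evaluated jointly:
   - *flat*: a run of successive differences below 1e-8 μV lasting more
     than 5 s (the flatness floor is a numeric convention; "flat" has no
     standard quantitative definition);
   - *high-frequency noise*: the SD of the residual above 20 Hz
     (signal minus its 20 Hz low-pass) below 4.5 μV removes the channel —
     i.e. channels whose high-frequency content has died. At realistic
     tens-of-μV amplitudes a live channel sits at 6–8 μV. The direction
     (`hf_rule`) and statistic (`hf_stat`: raw μV or a robust z-score
     across channels, the convention of population-based cleaning tools)
     are configurable;
   - *neighbor decorrelation*: Pearson correlation on 1–20 Hz band-passed
     signals against the channel's frozen montage neighbors, evaluated in
     5-s windows; the channel is removed when its best neighbor
     correlation falls below 0.7 in more than half of the windows. The
     windowed majority rule (rather than one whole-recording correlation)
     makes the criterion robust to brief high-amplitude transients, which
     are an epoch-rejection matter, not a channel fault: a single
     >10,000 μV transient otherwise dominates the whole-recording Pearson
     estimate through filter ringing and average-reference leakage.
   Bad channels are removed, never interpolated; every downstream feature
   touching a removed channel is missing for that participant, which is
   why per-feature sample sizes vary in the screening output.
5. **epoching** into 10-s epochs with 2-s overlap (onsets 8 s apart;
   trailing remainder discarded),
6. **epoch rejection**: an epoch is dropped when the maximum over channels
   of its peak-to-peak amplitude exceeds 10,000 μV or the minimum falls
   below 0.1 μV (the max/min-over-channels aggregation is the declared
   convention),
7. **minimum-length exclusion**: participants with fewer than six retained
   epochs (counted at 10 s each, i.e. under one minute) are excluded, with
   the reason logged. Manual exclusions (visual inspection) are accepted
   as an input list.

The montage adjacency is frozen in code; it was derived once from
published standard 10-20 spherical coordinates with a 52° angular-radius
rule, the only radius band that yields Cz ↔ {Fz, C3, C4, Pz} while keeping
the natural T3–C3/T4–C4 adjacency. The table is symmetric with minimum
degree 3.

## Feature space

Exactly 1,046 named features per participant, in frozen canonical order:

- **95 relative band powers** `relpower_{band}_{ch}`: one-sided multitaper
  PSD (7 DPSS tapers; with K tapers the time-half-bandwidth is
  NW = (K+1)/2 = 4, giving a 0.4 Hz half-bandwidth on 10-s epochs),
  integrated over delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma
  30–42 Hz (lower-inclusive, upper-exclusive) and divided by total
  0.5–42 Hz power. Normalization is per epoch, then averaged over epochs.
- **855 band coherences** `coh_{band}_{chA}_{chB}` (171 pairs × 5 bands,
  A before B in montage order): magnitude coherence
  |S_xy| / sqrt(S_xx·S_yy) with cross- and auto-spectra pooled over all
  tapers and epochs *before* the magnitude ratio, then averaged over
  in-band frequency bins. Pooling is deliberate: single-epoch multitaper
  coherence is strongly biased upward (identically 1 with one taper), so
  the per-epoch-then-average convention used for the other families is
  not meaningful for coherence. At 37 epochs × 7 tapers the null bias of
  the pooled estimator is ≈0.06, comfortably below 0.10.
- **95 time-domain statistics** `{sampen|skew|kurt|sd|mean}_{ch}`:
  computed within each epoch and averaged across epochs. Sample entropy
  uses embedding m = 2, Chebyshev tolerance r = 0.2·SD of the epoch,
  self-matches excluded, both template lengths counted over the first
  n−m starting points; a constant epoch gives 0 by convention and zero
  match counts give a missing value. Skewness and kurtosis are the
  bias-corrected Fisher (excess) conventions — the field has no single
  convention, so this one is declared.
- **1 alpha-presence flag** `alpha_present`: 1 when the smoothed
  epoch-averaged posterior PSD (O1, O2, Pz; all channels as fallback) has
  a local maximum in 7–13 Hz strictly exceeding the log-log interpolated
  1/f trend between the band edges by more than 25%. This is a simplified
  peak-prominence reimplementation of individual-alpha-frequency
  detection, exposed as a binary flag only; its parameters (search band,
  smoothing width, prominence fraction) are configurable.

## Screening: matching + weighted regression + Bonferroni

The propensity score is a maximum-likelihood logistic regression of group
on the demographic covariates, by default {age in months, sex}: the richer
anthropometric covariates are typically 20–40% missing in cohorts of this
design, and including them by default would silently drop a third of
participants. Scores feed either:

- **optimal full matching** (default): the partition of cases and controls
  into sets of one case with k controls or k cases with one control
  minimizing total within-set |logit(e_i) − logit(e_j)|. A full match is
  exactly a minimum-weight bipartite edge cover whose components are
  stars, so the solver uses the classical exact reduction to an
  assignment problem on reduced costs (each unit's cheapest partner
  subtracted; Hungarian algorithm on the padded matrix; uncovered units
  attached to their cheapest partner, with exact-distance ties spread by
  current partner load so that discrete covariates do not pile every case
  onto one control). Optimality is verified in the test suite against
  exhaustive enumeration on all random instances up to 6 units.

  A set-size restriction is applied by default (disable with
  `max_load_factor=None`): no unit may anchor more than
  ceil(2 × group-size ratio) partners; overloaded anchors shed their
  worst-fitting partners to the nearest under-loaded alternative. This is
  the full-matching analogue of the set-size restrictions in the standard
  matching tools, and it matters at strong imbalance: once covariates are
  near-balanced the propensity scores are near-tied, unrestricted full
  matching becomes arbitrarily degenerate, and a single control can anchor
  dozens of cases — collapsing the effective degrees of freedom of the
  weighted contrast to ~3, where no effect of any size can clear a
  Bonferroni screen. With the cap, the Satterthwaite df at 120 cases /
  20 controls stays ≥ ~10 across cohort draws. The restriction cannot
  bind on instances below 7 units, so small-instance optimality is
  unaffected. Weights: cases 1; a control in a set with T cases and C
  controls gets T/C, rescaled so control weights sum to the number of
  matched controls.
- **IPW**: stabilized inverse-probability weights (case p/e, control
  (1−p)/(1−e)) with symmetric score trimming to [0.01, 0.99].

Each feature is then regressed on [intercept, group, covariates] by
weighted least squares, using only participants non-missing for that
feature (weights renormalized to the subset's group sizes — the handling
of weights under missingness is a declared convention). The transform is
chosen from the observed values: logit for unit-interval features
(relative power, coherence; exact 0/1 nudged by 1e-6), log for strictly
positive unbounded features (SD, sample entropy), identity otherwise
(means, skewness, kurtosis, binary flags).

**Variance estimation.** The exposure test uses an HC3 (jackknife-style
leverage-corrected) sandwich with a t reference whose degrees of freedom
are the Satterthwaite match of the sandwich quadratic form under a
homoskedastic reference (a Bell–McCaffrey-style small-sample adjustment).
This matters: optimal-full-match weights concentrate the control side to
an effective sample size of ~25 of 40 nominal, and a plain HC0-normal
test is about threefold anticonservative at Bonferroni-relevant tail
levels. With the adjustment (and the set-size restriction above),
simulated null cohorts (240/40, 200 features) show a raw type-I error of
≈0.048 at the 5% level, tail rates within ~10% of nominal down to
p = 5e-4, and no Bonferroni-significant features at level 0.1 in ≈93% of
cohorts. The df depends only on the design and weights, so it is
computed once per missingness pattern; features sharing a pattern are
solved in one vectorized pass.

Family-wise control is Bonferroni, p_adj = min(1, m·p), with m the number
of features attempted (1,046 in a full run), not the number that survived;
features are declared significant below adjusted p = 0.1.

## Classification: nested LOOCV

For every left-out participant, the *entire* screening stack — propensity
model, matching, weighted regressions, Bonferroni ranking — is re-run on
the remaining participants only; the top K = 15 features by adjusted p
(ties by name) become candidates. Candidates missing in more than 20% of
the training split are dropped; remaining missing values are imputed with
training medians. Greedy forward selection then adds, at each step, the
candidate maximizing inner 5-fold stratified CV ROC-AUC of a ridge
logistic model whose regularization strength is grid-searched over
{0.01, 0.1, 1, 10, 100}; selection stops when no addition improves the
criterion by more than 1e-4, with a guaranteed non-empty selection. The
final model is refit on the whole training split (features standardized
to training mean/SD; penalty excludes the intercept; minority class
upweighted inversely to prevalence) and predicts the held-out probability.
If the nested propensity model fails (tiny splits can separate perfectly),
the split falls back to an unweighted screen rather than being lost.

The ridge logistic solver is a damped Newton optimizer written for this
package (verified against direct numerical optimization to 1e-4);
scikit-learn supplies only the stratified fold iterator. Metrics over the
out-of-fold probabilities: Mann–Whitney ROC-AUC (ties at one half),
trapezoidal PRC-AUC (no-skill reference = positive prevalence), stratified
percentile bootstrap 95% CIs (1,000 replicates), and the confusion matrix
at probability 0.5 with PPV/NPV (undefined cells reported as missing). A
baseline variant uses only {age, sex} as features, bypassing selection.

Per-sex univariate cutoffs scan the midpoints of consecutive sorted unique
feature values in both orientations and report the point minimizing
distance to the ROC top-left corner (ties: lower threshold, then the `>`
orientation).

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not biophysics. Defaults are the study conditions the pipeline targets:
246 cases / 42 controls (~6:1 imbalance), 300-s recordings at 256 Hz, sex
probabilities 0.87 (cases) vs 0.714 (controls) — confounding by
construction — ages ≈36 months (SD 14) truncated positive, and
Table-1-like missingness for the optional anthropometric fields.

Per recording:

- **1/f background**: independent per channel, PSD ∝ 1/f plus a white
  floor at 0.1 of the amplitude, broadband SD 20 μV.
- **Slow bilateral field**: one shared 1–6 Hz source with spatial sign +1
  on the left hemisphere and midline, −1 on the right, amplitude 40 μV,
  with mild per-channel gain modulation (SD 0.15). This is the spatial
  structure that keeps clean channels above the neighbor-correlation
  criterion: after average referencing, no isotropic smooth spatial
  covariance on this sparse 19-electrode graph can hold the apex channel
  above ~0.55 max-neighbor correlation (checked numerically for diffusion
  kernels, site sources with graph-distance decay, dipolar and quadratic
  harmonic fields, and Gaussian angular kernels), whereas the bilateral
  construction gives every channel a same-sign neighbor and max-neighbor
  correlations of ~0.75–0.95. Confining the field below 6 Hz keeps the
  alpha search band and the beta/gamma coherence spectrum clean.
- **Posterior alpha rhythm**: a shared narrowband source (center ≈
  N(10, 0.8) Hz, ±1 Hz width) weighted 1.0 on O1/O2 down to 0.1
  frontally, amplitude ≈ N(6, 2) μV, absent with probability 0.05.
- **Injected coherence effects**: for each configured channel pair and
  band, one shared band-limited Gaussian source added to both channels
  with the group's mixing gain. The source is scaled to the geometric
  mean of the two channels' in-band RMS, making the gain dimensionless:
  in-band magnitude coherence rises as ≈ g²/(1+g²) over the baseline
  (0.8 → ≈0.39), independent of band and background amplitude. An
  absolute-μV source scale would make the same nominal gain invisible in
  gamma under a realistic 1/f background, so the relative scale is the
  design choice that makes "gain" meaningful across bands.
- **Artifacts**: Poisson-distributed triangular transients (default
  0.2/min, 15,000 μV, 0.5 s) that exercise the peak-to-peak rejection
  rule.

Ground truth records each participant's group, the injected gains, and
the canonical names of the truly affected coherence features (empty when
case and control gains coincide).

What the generator does **not** emulate: physiological artifact morphology
(blinks, EMG), anatomically realistic source mixing and volume conduction,
non-stationarity, line-noise harmonics, or inter-site montage variations.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the declared generative assumptions — not
that the pipeline's scientific conclusions transfer to any particular
clinical dataset.

## Numerical and design choices

- All randomness flows from one root seed, split per stage with
  deterministic derivation; identical configs and inputs give
  byte-identical outputs.
- Problem sizes in the heavy validation suites are scaled for desk-scale
  runs: recovery-scale cohorts (120 cases / 20 controls) use 80-s
  recordings, smoke cohorts 70 s; generator defaults keep the full study
  conditions.
- EDF support: reading through mne; writing through a minimal 16-bit
  EDF writer (EDF is itself a 16-bit format; round trips are exact to
  quantization). The delimited-text format is the lossless default for
  synthetic cohorts.
- Degenerate inputs: zero total power → missing relative power with a
  warning; coherence from a single epoch and taper is identically 1 and
  flagged; constant signals give 0 sample entropy; perfectly separated
  propensity models raise with advice (or fall back inside LOOCV, above);
  rank-deficient feature regressions are skipped and logged.

## Known limitations

- The alpha-presence flag is a peak-prominence heuristic, not a full
  individual-alpha-frequency estimator; it returns a flag, not a
  frequency.
- Coherence is magnitude coherence; no phase-based connectivity (PLV,
  wPLI) and no source localization.
- The weighted-regression calibration statements hold under the
  generator's Gaussian-feature null; heavier-tailed features rely on the
  Bonferroni margin.
- LOOCV at strong class imbalance yields PPV/NPV driven largely by
  prevalence, as the confusion matrices make visible.
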