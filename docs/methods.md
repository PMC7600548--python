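# Methods

`eegaffect` implements a source-space analysis chain for affective EEG:
independent component analysis of multichannel scalp recordings, equivalent
current dipole localization of each component in a spherical head model,
cross-participant clustering of brain components, and emotional-state-specific
regression of normative valence/arousal ratings on the components' log band
power, with Fisher-z/Holm group inference. Because real affective-EEG cohorts
are rarely shareable, the package ships a forward simulator that generates
whole cohorts with *known* planted effects, so every stage can be validated
against ground truth.

## The analysis model

Stimuli live in the valence–arousal circumplex: each carries a normative
valence and arousal rating on [1, 9] with 5 neutral. Ratings above/below 5
define the *high*/*low* emotional state per axis, and the two binary states
define four quadrants (HVHA, HVLA, LVHA, LVLA). The default design is 160
stimuli, 40 per quadrant, presented over 8 sessions of 20 trials with 5 per
quadrant per session; each trial yields a 6-s EEG epoch.

Per participant the chain is:

1. **Preprocessing.** Continuous input is band-passed 0.5–45 Hz with
   windowed-sinc FIR filters (Hamming design, transition widths 0.5 Hz
   high-pass / 5 Hz low-pass, zero net delay) and downsampled to 512 Hz.
   Epoched data are cleaned with explicit robust statistics replacing visual
   inspection: channels at robust |z| > 5 of log-variance are interpolated by
   inverse-great-circle-distance weights on the electrode sphere; epochs with
   peak-to-peak > 200 µV or log-variance z > 4 are removed. Epochs are then
   concatenated, average-referenced, and projected onto their principal
   subspace of rank = channels − 1 (average reference) − interpolated
   channels.
2. **ICA.** Any square unmixing algorithm satisfying the decomposition
   contract is acceptable; extended Infomax is the default and a fixed-point
   negentropy (FastICA) option is provided. Components are returned in
   descending order of projected variance with a fixed convention — unit-norm
   scalp topography, largest-magnitude weight positive — so downstream
   features are deterministic.
3. **Dipole localization.** One equivalent dipole per topography: a coarse
   interior grid search (10 mm step, radius ≤ 0.9 R) where each candidate's
   moment is the linear least-squares solution against the 3-column lead
   field, followed by Nelder–Mead refinement of the location (stops when the
   simplex shrinks below 0.5 mm). Residual variance is measured in
   average-reference space and is scale invariant. Brain components must have
   RV ≤ 15 %, a dipole inside the brain compartment (radius ≤ 0.9 R), a
   non-rising 20–45 Hz log-log spectrum (muscle check), and < 60 % of
   topography energy on the 4 front-most electrodes (ocular check).
4. **Clustering.** Each brain IC is summarized by 18 features: 3 dipole
   coordinates, the top 10 principal components of the pooled topographies,
   and the top 5 principal components of the pooled 0–500 ms ERPs (resampled
   to 128 samples). Every dimension is standardized across ICs. K-means
   (k is an analyst choice, default 7; a silhouette diagnostic is exposed)
   is followed by one round of outlier pruning at 3 cluster SDs — the SD of a
   cluster about its centroid, i.e. the RMS member distance; the naive SD of
   the member *distances* would prune almost everything in 18 dimensions —
   and one membership recomputation. Only clusters with members from more
   than half of the cohort's participants are retained.
5. **Band power and regression.** Welch PSDs use 512-point (1 s) Hann
   segments with 128-point overlap (7 segments per 6-s epoch, 1 Hz bins).
   Band power is the mean PSD over in-band bins, edges inclusive (θ 4–7,
   α 8–13, β 14–30, γ 31–45 Hz); when a participant contributes several ICs
   to a cluster their PSDs are averaged bin-wise *before* the natural log.
   Four separate OLS regressions per cluster predict the normative rating
   from the four log band powers: valence within the high-valence epochs,
   valence within low-valence, arousal within high-arousal, arousal within
   low-arousal. All variables are standardized per participant (population
   denominator, so variances are exactly 1) before fitting. Evaluation is
   leave-one-participant-out: each fold trains on the pooled epochs of all
   other participants and records Pearson r, MSE, and coefficients on the
   held-out participant.
6. **Group inference.** Fold correlations are Fisher-z transformed; each
   cluster gets a one-tailed one-sample t-test (sample SD, df = folds − 1)
   against zero; p-values are Holm–Bonferroni corrected across the retained
   clusters of each (axis, state) family; the family significance level is
   0.025 because each axis is analysed in two states (0.05 / 2). Mean
   correlations are reported as tanh of the mean z.

## The synthetic cohort generator

The generator emulates a picture-viewing cohort: dipolar cortical sources
inside a homogeneous conducting sphere, one ocular artifact dipole, and
white + 1/f sensor noise, all in microvolt units.

**Forward model.** The surface potential of a dipole with moment `p` at
position `b` inside an insulated homogeneous sphere of radius `R` has the
closed form

    V(r_e) = (1 / 4πσ) · p · [ 2 d / d³ + (r_e + R d/|d|) / (R F) ],
    d = r_e − b,  F = R² − b·r_e + R|d|,

obtained by summing the boundary-corrected Legendre series analytically; the
central-dipole limit reduces to 3 p·r̂ / (4πσR²) and the implementation is
tested against an independently coded truncated-series oracle to < 1e-6
relative error. Electrodes are the 64-channel Biosemi layout, whose standard
digitization lies on a 95 mm sphere; that fixes R = 95 mm. Potentials are
average-referenced.

**Planted effects.** For a cortical source, the log power of band *b* in
epoch *e* is

    L(b, e) = baseline(b) + Σ_axis slope(b, axis, state_axis(e)) · z_axis(e)
              + participant band offset + epoch noise,

where `z_axis(e)` is the stimulus rating standardized *within the epoch's
(axis, state) subset* — effects are state specific by construction, mirroring
the separate high/low regressions. Band waveforms are band-limited Gaussian
noise synthesized in the frequency domain, multiplied by a slow log-normal
envelope (waxing/waning rhythms), and renormalized per epoch so the
time-domain band power equals `exp(L)` exactly. Each source also receives a
stimulus-locked Gabor deflection (source-specific latency and frequency,
participant-jittered amplitude ±20 % and latency ±10 ms) so ERPs are
informative, as in real stimulus-locked data. A weak 1/f background and the
ocular source (0.5–3 Hz, frontal, outside the brain compartment) carry no
rating information.

**Default conditions.** 25 participants × 160 epochs × 64 channels at
512 Hz (the post-downsampling rate; a 2048 Hz continuous path exercises the
filter/downsampler). Planted slope magnitude 0.5 per state-standardized
rating unit; epoch-level log-power noise SD 0.3; per-participant slope
jitter 20 % and dipole location jitter 5 mm SD ("individual differences");
per-source scalp contribution 3 µV RMS (ocular 6 µV); cohort SNR 10 (scalp
signal power over sensor noise power, 30 % of noise amplitude 1/f). The
ratings table doubles as the normative ratings used as the regression target;
no separate self-report is simulated. No reported effect sizes exist in
physical band-power units for this paradigm, so the slope magnitude is a
calibration choice made once: 0.5 yields per-epoch feature–rating
correlations around 0.3–0.5 after noise, at the upper end of plausibility for
a strong cortical effect, chosen so that a 6-participant study has useful
power.

**What the generator does not emulate.** Volume conduction uses a single
homogeneous sphere, not a BEM with realistic anatomy, so localization
accuracy statements are within-model only. Sources are stationary
band-limited processes with log-linear rating effects — there are no
nonstationarities across sessions, no muscle or line noise by default, no
blink transients (the ocular source is tonic), and anatomical labels do not
exist. Passing tests therefore demonstrate correctness of the machinery and
recoverability under a faithful but idealized signal model, not performance
on any real cohort.

## Desk-scale study conditions

Multi-seed validation studies use a scaled cohort: 6 participants, the full
160-trial design, 24 electrodes (an even subset of the montage — the
smallest at which single-dipole fits stay stable under realistic topography
contamination), 4 planted cortical sources + ocular, FastICA fitted on every
12th sample (the transform uses all samples), k = 4, 50 seeds. One cohort
analyses in ~15 s, a 50-seed study in ~12 minutes. The type-I-error study
runs at the feature level (6 participants, 40 epochs per state, 3 clusters,
400 replicates): cluster band-power tables are drawn independent of the
ratings and pushed through the regression and inference stages — exactly the
stages the calibration question concerns — because running 400 full
EEG-and-ICA cohorts would add nothing to that question.

## Numerical choices

- Band power uses the mean (not integral) over in-band bins; with 1 Hz bins
  the difference is a per-band constant absorbed by standardization. Natural
  log; base changes are likewise absorbed.
- Per-participant standardization uses the population denominator n so
  "variance 1" is exact; the choice cannot affect Pearson r.
- OLS includes an intercept; on standardized pooled folds it is ≈ 0 and is
  reported for transparency.
- Fold correlations at |r| = 1 are clamped to 1 − 1e-12 before atanh, with a
  warning. Zero-variance z across folds degenerates to p ∈ {0, 0.5, 1} by
  the sign of the mean. Folds with constant predictions or targets are
  flagged and excluded from the t-test.
- ICA determinism: a fixed seed reproduces the decomposition bit-for-bit;
  different seeds agree up to the inherent signed-permutation ambiguity.
- The dipole grid search caches per-(montage, step) orthonormal lead-field
  bases; refinement is skipped for clearly non-dipolar patterns
  (grid RV > 0.6), which cannot violate grid optimality.

## Known limitations

- **The fold-mean t-test is anti-conservative.** LOPO folds share training
  data, so fold correlations are positively correlated (empirically
  ≈ 1/(P−1) for P participants), inflating the one-sample t variance by
  roughly 2× independent of cohort size. On null cohorts the measured
  family-wise error is ~5–8 % at a nominal 2.5 %. This is a property of the
  inference procedure itself — testing fold-mean correlations with an
  ordinary one-sample t-test — which the package implements as specified;
  the validation suite measures and reports the inflation rather than hiding
  it. Users wanting calibrated inference should prefer permutation of the
  rating–epoch linkage.
- Significance of a *cluster* does not localize the effect to a band;
  coefficient summaries are descriptive (mean ± SD over folds), not tested.
- With few participants, a true source split across two k-means clusters can
  fail the majority-participant retention rule; the silhouette diagnostic
  helps choose k but no automatic selection is performed.
- EDF/BDF import is provided for continuous recordings only; epoching then
  requires explicit onset times.
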