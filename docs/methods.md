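# Methods

This document records the model, the estimators, the parameter choices and
the known limitations of the `ppgabp` pipeline.

## 1. Synthetic cohort model

Real simultaneous ABP/PPG recordings are not distributed with the package;
a parametric generator produces a cohort whose construction encodes the
physiological facts the analysis is meant to detect.

**ABP pulse train.** Each beat is a two-lobe Gaussian template on a beat
period T: a systolic lobe centered at 0.18 T (width 0.055 T) and a dicrotic
lobe at 0.45 T (width 0.09 T, relative amplitude 0.38), normalized to
[0, 1] and scaled to the subject's diastolic→systolic pressure span.
Beat-to-beat variability: timing jitter (2 % of T), amplitude jitter, and a
heart rate drawn from N(80, 8) bpm clipped to [50, 120].

**Pressure groups.** Systolic pressure is drawn uniformly inside each AHA
band: NT 95–115 mmHg, PHT 122–137 mmHg, HT 142–175 mmHg (kept strictly
inside the 120/140 boundaries so that labels recovered from the waveform
are unambiguous). Diastolic pressure follows dbp = sbp − (30 + 0.35 (sbp −
90)).

**ABP → PPG transfer.** The PPG is the ABP passed through a zero-phase
first-order low-pass (default 10 Hz), delayed by the pulse transit time,
rescaled, and corrupted with white noise. Group parameters:

| parameter | NT | PHT | HT | rationale |
|---|---|---|---|---|
| transit delay (ms) | 250 | 200 | 150 | stiffer hypertensive vessels conduct faster |
| delay jitter (ms, sd) | 12 | 12 | 12 | respiratory/vasomotor variation |
| PPG noise (fraction of signal sd) | 0.30 | 0.20 | 0.12 | weaker peripheral pulse in NT at fixed sensor noise |

**Electronic gain.** Each subject is assigned to a "low" or "high" gain
subgroup; the PPG pulse amplitude is drawn uniformly from the subgroup's
interval (0.6–0.75 or 2.2–3.0 a.u.) *independently of pressure*, modelling
a device's automatic gain. Consequently per-beat PPG amplitude carries no
information about pulse pressure — hypothesis H1 in the analysis. Setting
`CohortSpec(proportional_gain=...)` instead makes the PPG amplitude
proportional to the ABP amplitude; this is the positive control used in
the acceptance tests.

Determinism: all randomness derives from `numpy.random.SeedSequence(seed)`
spawned per record, so cohorts are byte-reproducible.

**Realism limits.** The generator produces a linear, quasi-stationary
coupling with additive Gaussian noise. It contains no reflected-wave
morphology changes, no nonlinear vascular compliance, no motion artifacts
beyond simple injected dropouts, and no inter-subject template variation
other than pressure/rate/delay/noise. Results on it validate the
*pipeline*, not clinical claims.

## 2. Preprocessing

- Band-pass 0.5–15 Hz, 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`, zero phase), then z-scoring per channel.
- Systolic peaks: `scipy.signal.find_peaks` with minimum distance 0.33 s
  and prominence 0.45 × (p95 − p5) of the filtered channel.
- Epochs: ten consecutive beats, bounded at the troughs preceding beats,
  forming a contiguous half-open partition of the record.
- Quality screen (any failure discards the epoch): ABP/PPG beat-count
  mismatch, inter-beat-interval CV > 0.25, beat-amplitude MAD-z > 4,
  > 1 % clipped samples, or a flat run longer than 0.1 s.
- Alignment: the PPG is shifted by the integer lag equal to the rounded
  mean offset between matched PPG and ABP peaks; morphology correlation is
  computed on the aligned pair.
- Group labels are re-derived from the measured ABP (mean systolic peak
  pressure; < 120 NT, 120–140 PHT, ≥ 140 HT) rather than read from truth.

## 3. Time-domain similarity

**Morphology (H2).** Pearson r between the aligned, normalized ABP and PPG
sample vectors per epoch, averaged per subject. On default cohorts the
group means are ≈ 0.986 (NT), 0.991 (PHT), 0.994 (HT) — ordering driven by
the group noise levels.

**Amplitude (H1).** Per-beat amplitudes are estimated *selection-free* on
8 Hz zero-phase-smoothed copies of the raw channels: amplitude = mean of a
5-sample window at the peak minus the mean of the pre-upstroke window
[peak − 0.35 T, peak − 0.15 T]. A min-picked foot would have a
noise-level-dependent negative bias that, combined with group-dependent
noise, manufactures a spurious negative ABP-vs-PPG amplitude correlation;
the windowed means remove that bias. Correlations are computed within each
electronic-gain subgroup; amplitude coupling is rejected when every
subgroup has |r| < 0.3.

## 4. VAR modelling and spectral decomposition

Each epoch (zero-mean channels) is fit as a bivariate VAR(p) by
multivariate least squares without intercept. The residual covariance uses
divisor (n − p) − 2p. The lag matrices are stored in regression form Φ(k);
the A(0) = I moving-average convention A(k) = −Φ(k) is exposed as
`VARModel.a_matrices`.

**Order selection.** The Schwarz–Bayes criterion
ln det Σ̂_ML(p) + (ln n_eff / n_eff) · 4p is evaluated for p = 1…p_max on
the common sample t = p_max…n−1 (one Gram matrix, nested sub-solves). Each
epoch contributes its optimum; the group's order is the mode (ties → the
smaller order). Default p_max = 40 (capped per group at (min epoch length
− 4)/3), chosen so the search space spans the largest transit delay
(250 ms = 31 samples at 125 Hz). Typical selected orders are 18–26.

**Spectral form.** A(f) = I − Σ_k Φ(k) e^(−i 2π f k / fs), H(f) = A(f)⁻¹
(closed-form 2×2 inverse), S(f) = H Σ H*. Grid: 0 to fs/2 in 0.1 Hz steps.

## 5. Connectivity measures

With element (i, j) meaning "channel j drives channel i" (channel 0 = ABP,
1 = PPG, so ABP→PPG is element (1, 0)):

- COH = |S₀₁| / √(S₀₀ S₁₁)
- pCOH from P(f) = S(f)⁻¹ (genuine inversion; in the bivariate case
  |pCOH| = |COH| is an exact identity and is monitored as a numerical
  diagnostic, observed ≤ 1e-14)
- PDC: |A_ij(f)| normalized by its column norm
- DTF: |H_ij(f)| normalized by its row norm
- ffDTF: DTF numerator with the row denominator summed over the whole grid
- dDTF = ffDTF × pCOH on the off-diagonal elements

Each measure is summarized per epoch as its maximum over 1–10 Hz and
averaged over epochs per subject.

## 6. Statistics

Pairwise comparisons use the two-sided Wilcoxon rank-sum test (exact null
when both groups have ≤ 10 subjects and no cross ties, asymptotic with tie
correction otherwise) at α = 0.1; the three-group comparison uses
Kruskal–Wallis at α = 0.05. Frequency-resolved profiling applies the
rank-sum test at every grid frequency in 1–10 Hz and merges contiguous
significant frequencies into intervals. No multiplicity adjustment is
applied across measures or frequencies; outputs are labelled unadjusted.

## 7. Classification

Features: per-subject band-max COH, PDC, DTF, ffDTF, dDTF (ABP→PPG);
PHT subjects are excluded. Evaluation is leave-one-out with a fresh
`StandardScaler` + classifier pipeline per fold, so no statistics leak
from the held-out subject. The primary model is a feed-forward network
with one 10-unit logistic hidden layer trained by L-BFGS (deterministic
per seed); baselines are LDA, a pooled-diagonal-covariance linear
discriminant, regularized QDA, 5-NN, depth-4 decision tree, Gaussian
naive Bayes and an RBF SVM. Up to 5 % failed folds are tolerated and
reported; more raise an error. ROC points come from pooled held-out
scores.

## 8. Open design decisions and known behaviors

- **ffDTF trend sign.** On full-size cohorts the ABP→PPG ffDTF *decreases*
  from NT to HT. The measure still separates the groups strongly
  (p ≈ 1e-5–1e-7); the sign depends on how the selected VAR order
  distributes the transfer energy across the grid relative to the transit
  delay and should not be interpreted physiologically.
- **PDC = DTF columns in the bivariate case** arise whenever one
  off-diagonal of A(f) is negligible; the p-value tables may therefore
  show identical rows for PDC and DTF.
- **Amplitude estimator residual.** The per-subgroup amplitude correlation
  on ~10 000 beat pairs retains a record-sampling fluctuation of order
  1/√(subjects); observed values are within ±0.15 of zero across seeds,
  comfortably inside the |r| < 0.3 rejection threshold, but single extreme
  seeds can approach it.
- **No multiplicity correction** in the frequency profiles (by design,
  matching the exploratory protocol); interval endpoints are descriptive.

## 9. Key defaults

| parameter | default | unit | notes |
|---|---|---|---|
| sampling rate | 125 | Hz | generator and pipeline |
| filter band | 0.5–15 | Hz | Butterworth order 4, zero phase |
| beats per epoch | 10 | — | protocol unit of analysis |
| frequency resolution | 0.1 | Hz | spectral grid |
| analysis band | 1–10 | Hz | band-max summaries and profiling |
| p_max | 40 | lags | order search bound (≈ 320 ms) |
| α pairwise / 3-group | 0.1 / 0.05 | — | unadjusted |
| H1 rejection threshold | 0.3 | |r| | per gain subgroup |
| cohort | 43/40/37 | subjects | NT/PHT/HT, 120 s records |
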