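# Methods

This note documents the models, estimators, numerical choices and
known limitations of `netinfodyn`, in the order data flows through the
package.

## 1. The linear-Gaussian information decomposition

The network is a zero-mean vector stochastic process
X_n = [X_{1,n} … X_{M,n}]ᵀ assumed jointly Gaussian and Markov of
order m, so its past can be truncated at m lags.  For a target j the
entropy of the present sample decomposes as H_j = S_j + T_j + N_j
(storage + joint transfer + new information), and every term is a
log-ratio of *partial variances* — prediction-error variances of
X_{j,n} given selected past histories.  All logarithms are natural;
all measures are reported in nats.

The identity is algebraically telescoping: whatever four positive
variances enter the formulas, H − (S+T+N) cancels exactly.  The
package exploits this: the identity holds to machine precision for
every backend, and the tests assert it at 1e−8 rather than rely on it.

### Partial variances

Two routes are implemented.

**State-space (default).**  The fitted VAR(m) is put in innovations
form with state Z_n = [X_{n−1}; …; X_{n−m}], observation
X_n = C Z_n + U_n, C = [A₁ … A_m], state noise K U_n.  Removing
processes from the observation equation leaves a state-space model
with correlated state and observation noise; its steady-state filter —
obtained from the discrete algebraic Riccati equation (DARE) with
cross-covariance term — gives the innovation covariance of the
retained processes, i.e. the prediction-error variance of the target
given the *infinite* past of the retained set.  The full-model partial
variance σ²_{j|j,s} is simply Σ_jj of the fit (the full model is the
unreduced submodel), and the process variance σ²_j comes from the
discrete Lyapunov equation.

**Regression (verification).**  Explicit OLS of the target's present on
each designated lag set, with residual variances normalized by
1/(N − m).  Nesting of the lag sets makes S, T and every conditional
transfer exactly non-negative in finite samples.

**The two routes estimate slightly different population quantities for
reduced sets.**  A subset of a VAR(m) network is generally not Markov
of order m: its optimal predictor involves the infinite past.  The
regression route truncated at m lags therefore exceeds the steady-
state (Riccati) value whenever the removed processes carry long
memory; gaps up to ≈0.16 nats occur in storage for strongly periodic
nodes.  The routes agree in the deep-lag limit, and that is how they
are cross-validated: the oracle regressions use 20 lags (never fewer
than m), at which depth all three benchmark presets agree with the
Riccati values to well under 1% at 10⁶ samples.

### Finite-sample conventions

On data, H and S use the mean square of the same samples the
regressions predict (the last N − m points, no mean subtraction, since
the series are standardized and the regressions have no intercept).
This keeps all finite-sample measures exactly nested.  With
standardized rows H_j ≈ ½ ln 2πe ≈ 1.419 always; the decomposition is
the informative part.

Estimator bias is real and documented rather than hidden: at N = 300,
storage is biased low by up to ≈0.05 nats on the benchmark (AR
coefficient attenuation) and transfer high by ≈0.01 nats (overfitting);
both fall by roughly an order of magnitude at N = 3000.  The suite
tests this consistency, not unbiasedness.

### Numerics

The DARE is solved by `scipy`'s Schur-based solver with a fixed-point
fallback (tolerance 1e−12 on successive iterates, max 10⁴ iterations);
the solution is always verified by substituting back (residual below
1e−6 relative) so a silent wrong value cannot propagate.  Unstable
specs or fits are rejected with the offending spectral radius.  An
unstable *fitted* window (possible on short noisy data) is not
silently regularized: its measures are computed with the regression
backend, the window is flagged, and it is excluded from consensus.

## 2. VAR fitting and order selection

Least squares without intercept; residual covariance with 1/(N − m).
AIC(p) = N_eff ln det Σ̂(p) + 2pM² is minimized over p = 1…12 with all
candidates fitted on the common sample dropping the first 12 points,
so likelihoods are comparable; ties go to the smaller order.  The
maximum order 12 is a configuration default (unspecified upstream);
typical selected orders on synthetic recordings are 4–7.

## 3. Synthetic data

### Benchmark VAR networks

* `independent` — seven uncoupled AR(1) nodes with self-couplings
  0.9 … 0.2 (null topology, storage spread);
* `chain3` — X1→X2→X3 at coefficients 0.4, selfs 0.5: the mediation
  testbed (T_{1→3|2} is exactly zero);
* `paperlike7` — seven nodes named after the physiological network.
  Couplings (lag 1): RESP→RR 0.40, RR→RESP 0.30, RR→PAT 0.30,
  RESP→PAT 0.30, delta→RR 0.30, beta→RESP 0.30; self-couplings 0.60
  (RR), 0.55 (RESP), 0.30 (PAT), 0.20–0.30 (bands); unit innovations.
  The self-couplings were chosen once so the model-implied storage is
  ordered RR > RESP > PAT > bands — the qualitative pattern the
  estimator chain must reproduce.  Spectral radius 0.92.

Simulation draws Gaussian innovations via Cholesky and discards a
500-sample burn-in (ample for spectral radius ≤ 0.95); identical seeds
give bit-identical output.

### Raw recordings

The generator reproduces the *dynamical* structure the pipeline must
recover, not signal morphology:

* **Respiration** (25 Hz): sinusoid at f_resp plus white noise
  (defaults: 0.25 Hz, noise SD 0.05).
* **Beats**: RR_n = RR_mean (1 + g sin φ_resp(t_n)) + ε — respiratory
  sinus arrhythmia as pure phase coupling (defaults RR_mean 0.8 s,
  g 0.08, jitter SD 0.02 s).
* **ECG** (250 Hz): one 40 ms raised-cosine spike of amplitude 1 per
  beat on baseline noise SD 0.05.  The spike length is forced odd so
  its maximum is a single sample — otherwise beat placement and
  template alignment jitter by one sample.
* **PAT and BVP** (64 Hz): per-beat PAT = 0.25 + 0.03 sin φ_resp +
  noise (SD 3 ms), clipped to [0.05, 0.55] s.  The 30 ms respiratory
  modulation is within the physiological range for wrist pulse arrival
  (pre-ejection period effects) and is deep enough that the 64 Hz
  estimator's irreducible ±half-sample quantization does not mask it.
  Each pulse (80 ms raised-cosine upstroke, 300 ms cosine decay) is
  evaluated analytically at a *continuous* onset so the steepest-rise
  point falls exactly at beat + PAT; rendering on the sample grid
  first was found to corrupt the ground truth by up to half a sample.
* **EEG** (256 Hz): sum over δ, θ, α, β of band-limited Gaussian noise
  (4th-order Butterworth, forward-backward) scaled by a positive
  envelope, exp of an AR(1) at 1 Hz (ρ 0.95, SD 0.25), linearly
  interpolated.  Envelope parameters are free choices: the upstream
  problem does not characterize the statistics of real band-power
  series beyond their appearance, so nothing here is a fit.

Stored ground truth: beat times, per-beat RR and PAT, respiratory
phase at beats, and the 1 Hz band envelopes.

What passing tests show — and do not show.  The generator has no
ectopic beats, motion artifacts, P/T waves, electrode noise, or
nonstationary respiration; passing end-to-end tests demonstrates that
the measurement chain is correct under its stated model, not that it
is robust to every pathology of real wearable data.

## 4. Preprocessing

* **ECG filter**: 4th-order Butterworth band-pass, 1–20 Hz half-power
  corners, applied forward-backward (zero phase preserves R timing).
* **R peaks**: provisional pass at 0.6 × the 95th percentile of the
  rectified signal with a 250 ms refractory; template = mean of ±60 ms
  around the 20 largest provisional peaks; normalized cross-
  correlation thresholded at 0.6 with the same refractory; the R time
  is the maximum of the aligned template.  A matched candidate must
  *also* clear the amplitude threshold: shape alone is not specific,
  because band-limited noise correlates well with a smooth template.
  A flat or beat-free record raises an explicit no-beats error.
* **RR series**: rr_k = t_{k+1} − t_k, attributed to the closing peak
  (the value exists only once the interval closes).  Automated ectopic
  handling replaces visual editing: an interval outside [0.7, 1.3] ×
  an 11-beat running median triggers a merge when two adjacent short
  intervals sum to a plausible beat (false peak), otherwise the value
  is bridged by interpolation (missed/ectopic beat).
* **Respiration at beats**: nearest-sample value at each R time.
* **PAT**: per beat, the first-difference maximum of the BVP in
  (peak, peak + min(next RR, 0.6 s)], at the half-sample convention
  (d_i sits at (i+½)/fs).  The 0.6 s cap is far above wrist arrival
  times.  Beats whose best upstroke is below a quarter of the median
  upstroke strength are marked missing and bridged; more than 20%
  missing is a hard failure.
* **1 Hz resampling**: cubic spline through beat-time values evaluated
  on integer seconds inside the beat span (never extrapolating).
* **Band powers**: 2 s epochs, 1 s hop, mean-detrended, rectangular-
  window periodogram summed over bins whose centre lies in
  [0.5, 3), [3, 8), [8, 12), [12, 25) Hz (half-open bands prevent
  double counting).  A D-second record yields D − 1 values stamped at
  epoch centres 1 … D−1 s, so the peripheral grid can be cropped to
  identical timestamps without padding.
* **Window**: 300 samples starting 180 s into resting records, 60 s
  (configurable to 120 s) after task onset.
* **Stationarity screen**: 10 random 50-sample subwindows, each tested
  against the pooled remainder for mean (Welch t) and variance
  (two-sided F), level 0.05.  The series fails when more than 3 of the
  20 tests reject.  The count threshold is Monte-Carlo calibrated:
  overlapping subwindows make the tests positively dependent and the
  rejection count overdispersed, so the binomial-looking ">2 of 20"
  rule has a ~12% false-alarm rate while ">3" has ~5% and still fails
  step (3 SD) and trend (4 SD) alternatives essentially always.  A
  failing row is flagged and logged, never dropped — EEG band-power
  rows, being heavy-tailed and slowly modulated, are flagged often on
  synthetic data; this is honest behavior of the screen, not an error.
* **Standardization**: zero mean, unit variance per row, 1/N
  convention (which makes H = ½ ln 2πe exact on standardized rows).

## 5. Link inference and consensus

The F-test compares nested OLS models on the same N − m samples:
full (all M·m lags) vs. restricted (omitting the m lags of the removed
sources), F = ((RSS_r − RSS_f)/q)/(RSS_f/d) with q = m·|removed|,
d = (N − m) − M·m, no intercepts.  The restricted model genuinely
re-estimates all remaining coefficients.  Under Gaussian innovations
this test is essentially exact at N = 300: on the fully mediated null
pair of the chain benchmark the measured type-I error over 1000
windows is ≈5%.

No multiple-testing correction is applied across the 42 directed
pairs: per-test p < 0.05 decisions are aggregated across subjects, and
the ≥7-of-18 consensus threshold provides the family-wise control (a
null pair reaches 7/18 with probability ≈ 3·10⁻⁵, and the "thick"
threshold >12 is unreachable by chance).  A Benjamini–Hochberg option
exists but is off by default.

## 6. Pipeline and problem sizes

The study driver processes each subject-state recording independently
(order selected per window, as the per-window Markov approximation
demands), writes tidy CSV artifacts with a provenance sidecar (config
hash, seed, order, stability flag), and excludes unstable fits from
consensus with a logged list.  Defaults generate REST records of 500 s
and task records of 380 s so the 300-sample windows fit behind their
offsets with margin.

Problem sizes used by the validation suite were chosen to give tight
Monte-Carlo error at interactive runtimes: 10⁶-sample realizations for
oracle agreement (sampling error ≪ the 2% band), 1000 replicates for
test calibration (SE ≈ 0.7 percentage points), 20 replicated
18-subject studies for topology recovery, and 40/20 replicates at
N = 300/3000 for the bias study.  A full 18-subject, 3-state synthetic
study runs end to end in well under 15 minutes on one CPU (measured:
≈20 s per subject including generation).

## 7. Known limitations

* Linear-Gaussian measures only: nonlinear or non-Gaussian coupling is
  invisible by construction; zero-lag (instantaneous) effects are
  deliberately out of scope.
* The F-test's exactness degrades if the selected order underfits;
  AIC with maximum 12 is a pragmatic, not optimal, choice.
* Storage at N = 300 carries a known downward bias (~0.05 nats on the
  benchmark); comparisons across conditions at fixed N are safe,
  absolute values are not.
* The stationarity screen tests only first and second moments on one
  subwindow scale.
* Band-power series violate the Gaussianity the entropy formulas
  assume (they are non-negative and skewed); the linear measures
  remain well-defined second-order quantities, as is standard
  practice, but their entropy interpretation is approximate.
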