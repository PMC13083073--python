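# Methods

## Signal model and what the generator emulates

A synthetic trial is `x_c(t) = n_c(t) + A·w(t)·b_c(t)`: 1/f background
noise `n_c` (spectral slope `noise_exponent`, default 1.0, unit RMS per
channel), a raised-cosine taper `w(t)` over the post-stimulus burst window
(0–800 ms for delta, 0–400 ms for theta — slightly longer than the PLV
averaging windows so the analysis window sits inside strong signal), and a
band-carrier burst `b_c` (2 Hz delta, 5.5 Hz theta). The burst amplitude is
set by `snr_db` (default 10 dB burst-peak RMS over background; the analytic
PLV oracle uses 30 dB so the jitter mechanism, not the noise floor, sets
the measurement).

Phase coupling is directional. Driver channels (F3, F4, C3, C4) draw
independent uniform burst phases per trial. Each coupled target channel
receives a burst component with phase `φ_driver + lag + ε`,
`ε ~ vonMises(0, κ)`, so a driver–target pair has trial-asymptotic
PLV = I₁(κ)/I₀(κ) — a closed form that the tests use as an oracle. A
target listed under several drivers (P8, coupled to both F3 and F4 in the
default effect set) carries an equal-weight superposition of driver-locked
components. Channels outside the coupling graph get independent phases.

The default cohort reproduces the study conditions: 30-channel 10–20
montage, groups HC/PD-MCI/PDD/DLB of 24/20/18/11, per-condition retained
trial counts drawn from the reported means ± SD (truncated at 5), group
ages from the reported distributions. Patient-like groups scale κ on six
designated pairs only (F3-TP8, F3-P8, F3-O2, F4-T7, F4-P8, F3-T8) by
multipliers HC 1.0 / PD-MCI 0.7 / PDD 0.35 / DLB 0.5 with base κ = 2.5 —
chosen so the HC planted-pair coherence sits near 0.74 and the PDD near
0.4, comfortably inside the dynamic range the PLV estimator resolves at
~15 trials. A per-subject lognormal coupling scale (σ = 0.15) induces
between-subject coherence spread, and MMSE / oddball-error covariates are
linear in the model-implied mean coherence `c` (MMSE = 14 + 20·c + ε,
error = 12 − 14·c + ε, ε ~ N(0, 1.5)), giving realistic ranges (MMSE
~21–29) and a recoverable generating β.

What the generator does **not** emulate: volume conduction (channels are
spatially independent except for the planted coupling), ocular/EMG
artifacts, non-stationary background, electrode drift, or condition
differences beyond trial counts. Consequences: (i) passing recovery tests
shows the analysis machinery is correct, not that real scalp EEG satisfies
its assumptions; (ii) the CSD stage — whose purpose is to undo volume
conduction — is *omitted from the synthetic recovery studies*, because on
spatially independent channels it only smears the planted target signals
into neighbouring electrodes and contaminates non-planted pairs. CSD
remains the default in the CLI path for real recordings and has its own
validation (uniform-map annihilation, reference invariance, dense-solve
agreement).

## Analysis choices

* **Filtering** — zero-phase 4th-order Butterworth, separate high-pass
  (0.01 Hz) and low-pass (60 Hz) cascades; a joint band-pass design is
  numerically ill-conditioned at a 0.01 Hz edge. The high-pass has a ~16 s
  time constant, so its edge transients are physical; epochs are cut from
  record interiors.
* **CSD** — Perrin-style spherical splines, g-kernel exponent m = 4,
  Legendre truncation 10, λ = 10⁻⁵ on the spline diagonal, zero-sum
  constraint via an augmented system; head radius fixed at 1
  (dimensionless sphere), so outputs are µV/m² up to that scale. Built-in
  electrode positions are constructed from the defining 10–20 arc geometry
  (ring at 72° polar, arcs subdivided in 10/20% steps) — a stand-in for
  the unreported digitized positions.
* **Wavelets** — complex Morlet, 3 cycles, unit-L2 (Gabor) normalization,
  support truncated at ±4σ_t, frequency-domain convolution with "same"
  alignment; 30 log-spaced bins inclusive of band edges. Samples within
  2σ_t of epoch borders are flagged invalid per frequency; the long
  pre/post windows exist to absorb exactly these edge effects.
* **PLV windows** — half-open, `round(W·fs)` samples from onset (154
  samples for delta 600 ms at 256 Hz); bins averaged with uniform weights.
  "Weighted average coherence" per subject is an unweighted mean over the
  40 pairs (target condition) by default, with an optional per-pair weight
  vector — the weighting is otherwise unspecified upstream.
* **IQR exclusion** — linear-interpolation quartiles, strict-"beyond"
  3×IQR fences (boundary values kept), applied per group × measure. The
  rule is *not* universally idempotent (removing a far point reshapes the
  quartiles); the property holds in the intended bulk-plus-gross-outliers
  regime and is tested there.
* **Graphs** — edge length 1/PLV for shortest paths (standard for
  coherence weights); fixed 10% density with `floor()` edge count and
  lexicographic tie-break; full 30-channel matrices by default (a
  pair-set-restricted mode exists; the upstream description never names the
  node set). Clustering is Onnela geometric-mean triangles on max-weight
  normalized weights; nulls are Maslov–Sneppen double-edge swaps (10×
  edge-count) with weights re-permuted over the rewired edges; efficiency
  reported raw at fixed density, only σ normalized.
* **LASSO path** — glmnet convention authored in-package (warm-started
  IRLS + cyclic coordinate descent, numba-compiled): features standardized
  inside the procedure (population SD), unpenalized intercept, 100 λ values
  log-spaced from λ_max down by 10⁻²; per-observation binomial deviance;
  λ_1se = largest λ within one SE (over folds) of the minimum; stratified
  folds with one subject per observation. Tests verify KKT optimality and
  that the solutions do not lose to liblinear on the same objective
  (liblinear penalizes the intercept, which is why it is the oracle, not
  the implementation). K-sparsity labels: 0 / 1 / 2–5 / ≥6.
* **Bolasso** — 100 stratified resamples, each selecting at its own
  cross-validated λ_min (5-fold, 50-point path inside resamples — a
  deliberate economy; the full-data CV uses 10 folds and 100 points),
  retention at ≥85% selection frequency; threshold 0 degrades to "ever
  selected".
* **Validation statistics** — permutation p reported both as printed
  (b/M, can be 0) and smoothed ((b+1)/(M+1)); an exhaustive-enumeration
  mode exists for small n. BCa intervals via `scipy.stats.bootstrap`.
  Confusion metrics at the 0.5 out-of-fold probability operating point (no
  threshold rule is specified upstream; this is the documented choice);
  undefined ratios are reported missing, not 0. Per-feature "AUC mean ±
  SD" is a stratified subject bootstrap with orientation fixed on the full
  sample (pROC-style automatic direction). Welch tests stand in for
  mixed-model EMM contrasts; the omnibus repeated-measures ANOVA is out of
  scope by design.
* **Embedding** — axes are raw coherence values of the top-3 pairs (by
  |LASSO coefficient|, or inter-group variance in the CLI stats stage
  before a classifier has run); ellipsoids are axis-aligned per-group
  mean ± 1 SD; separation tested per axis against the reference group on
  z-scored values with FDR over axes.

## Validation-study problem sizes

The study-scale suite (tests) uses: PLV oracle at 200 trials × 5
replicates per κ ∈ {0, 1, 2, 4}; 50 brute-force random graphs ≤ 12 nodes;
20 seeds × 100 nulls for small-world checks; 1000 datasets × M = 200 for
permutation calibration; 1000 repetitions × 1000 resamples for BCa
coverage; 20 end-to-end repetitions of a 24-vs-18 cohort (with matched
null-effect runs); 200 cohort repetitions for regression recovery. The
reproduction script (`scripts/acceptance.py`) reports the same quantities
at reduced counts, recorded per entry in its JSON output. At κ = 0 the
finite-trial expectation of the PLV estimator is √π/(2√N) ≈ 0.063 at
N = 200, not 0; the null check targets that value.

## Known limitations

* Real-EEG stages (vendor readers, CSD on caps, ICA-level artifact
  handling) are exercised only on synthetic or in-memory data; ICA is
  replaced by amplitude-threshold rejection.
* The planted-effect design makes feature recovery unambiguous; correlated
  effects spanning many pairs (as real disease likely produces) would make
  Bolasso's retention set less interpretable.
* Pooled out-of-fold AUC under the null is high-variance on 42 subjects
  (fold-intercept artifacts push single runs far from 0.5 in both
  directions); only its mean over repetitions is a calibrated quantity.
* The 0.01 Hz high-pass leaves ~16 s edge transients; continuous records
  shorter than a few minutes should not be filtered with it.
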