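# Methods

`prepercept` implements a complete analysis chain for testing whether
prestimulus directed coupling between two cortical nodes biases the reported
content of an ambiguous (face/vase) stimulus, together with a synthetic
cohort generator whose ground truth is known, so that every stage can be
validated by parameter recovery rather than by comparison with unavailable
recordings. This note documents the generative model, the estimators, the
statistics, and the numerical and design choices a maintainer would want to
know.

## 1. Synthetic cohort generator (`prepercept.simulate`)

### Generative model

Two sources — a V1-like node and an FFA-like node, fixed package-wide as
channel order `(V1, FFA)` — follow a bivariate VAR(5) at 250 Hz. Each
channel carries an AR(2) resonance whose lag-1 coefficient is chosen so the
spectral peak sits exactly at 10 Hz (for AR(2), `cos(w_peak) =
-a1 (1 - a2) / (4 a2)`); the default pole radius 0.8 gives an alpha bump of
a few Hz half-width over a broadband low-frequency background, i.e. spectra
concentrated below ~25 Hz with a clear ~10 Hz peak. Directed coupling is a
real coefficient added to the FFA→V1 entry at lags 2–3 (two lags, so the
interaction has a genuine time delay and nonzero imaginary coherency). The
companion-matrix spectral radius is checked at construction; unstable
configurations are rejected. Because the coupling is unidirectional the
companion matrix stays block-triangular, so coupling alone can never
destabilize a stable base model.

Condition structure per trial:

- the report label is an i.i.d. Bernoulli draw (`p_face`, default 0.5);
- during the **prestimulus** samples (t < 0) the FFA→V1 coefficient equals
  `coupling_vase` (default 0.02) on vase trials and `coupling_face`
  (default 0.035) on face trials; after stimulus onset both conditions
  revert to the base (uncoupled) coefficients, so post-stimulus connectivity
  is uninformative by construction;
- on face trials an amplitude-modulated **gamma burst** (60 Hz, Hann
  envelope over 0–0.35 s, amplitude 0.5, random phase per trial) is added to
  the FFA source, and smooth Gaussian **evoked bumps** are added to the
  sources (V1 at ~100 ms, σ = 20 ms, amplitude 1.5; FFA at ~160 ms,
  σ = 25 ms, amplitude 1.3). The Gaussian envelope keeps evoked energy below
  ~25 Hz, so the gamma-range category difference comes from the burst alone;
  the two bump latencies are what makes the decoder's source maps select the
  V1-like point in the 50–120 ms window and the FFA-like point in the
  120–200 ms window.

Sources are normalized to unit stationary SD (per channel, from the
companion-form Lyapunov equation of the base process), so all amplitudes
above and the sensor noise are in units of the ongoing activity's SD.
Epochs span −1.0 to +0.5 s; a burn-in of
`max(10·order, ceil(12/(1−spectral radius)))` samples is discarded per
trial so returned samples are stationary for any admissible pole radius.

Sensor projection multiplies the sources by a 30 × 2 mixing matrix of
smooth random unit-norm topographies (fixed per cohort seed) and adds
i.i.d. Gaussian sensor noise (SD 0.25). Per-subject heterogeneity: one
"excitability" factor `g ~ max(0.1, 1 + N(0, 0.3))` drawn per subject
scales the coupling difference, the gamma amplitude, and the evoked
amplitudes (`subject_factor_mode="shared"`; `"independent"` draws three
separate factors, `"none"` disables jitter). The shared mode is what makes
the per-subject maxima of feedback Granger, gamma effect, and decoding
accuracy positively correlated across subjects, emulating the
interindividual-covariation analysis.

Seed policy: the cohort seed spawns per-subject seeds through
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and subjects
are independent.

### Effect-size defaults and what they produce

The defaults were fixed once, from design simulations, to place every
analysis in a realistic regime: single-subject feedback Granger on
reconstructed sources ≈ 0.1–0.35 (face) vs ≈ 0.05–0.1 (vase) with a ~10 Hz
peak; coherence ≈ 0.3–0.6 with a clear alpha peak; a ~1.5–2× 60-Hz power
increase on face trials in FFA; decoding AUC rising from chance at t = 0 to
≈ 0.7–0.8 and returning toward chance, with chance-level prestimulus AUC.

### Known divergences from real data

- Injecting coupling through VAR coefficients necessarily adds power to the
  target node: face-trial V1 has ≈ 10–20 % more prestimulus variance
  (mostly alpha-band, with a ~1 % broadband floor excess). The real study
  reported no prestimulus power differences; the synthetic prestimulus
  power contrast in V1 is therefore expected to be *significant* at full
  cohort size. The power stage is retained as an analysis, but its null is
  not emulated — a limitation inherent to coefficient-based coupling.
- The sensor array is homogeneous (no magnetometer/gradiometer distinction,
  no channel-type scaling), there is no artifact simulation, and source
  reconstruction is the pseudo-inverse of the known mixing rather than an
  anatomical inverse operator. Passing tests therefore validate the
  *analysis chain*, not robustness to head-model error or artifacts.

## 2. Spectral estimation (`prepercept.spectral`)

Multitaper estimates use DPSS tapers (scipy), unit-energy normalized, with
the taper count bounded by `floor(2·NW) − 1`. All spectra are two-sided
densities per Hz, `S(f) = |Σ_t v(t) x(t) e^{−2πift}|² / fs`, so the
two-sided integral equals the windowed variance (Parseval; tested). The only
detrending is per-window mean removal.

- **Prestimulus cross-spectra**: the full 1-s window with time-bandwidth 2
  (3 tapers, ±2 Hz smoothing); the frequency grid is the window's natural
  1-Hz rfft grid. For spectral factorization the tapered segments are
  zero-padded (factor 8) onto a denser grid: the minimum-phase factor's
  impulse response must be representable within the grid's lag range, and on
  the natural grid its truncation leaves a reconstruction-error plateau far
  above tolerance. Statistics are always evaluated on the natural (Rayleigh)
  grid restricted to the declared band — padding adds no information.
- **Time-frequency power**: sliding windows (default widths 0.3 s and the
  0.1-s control, 50-ms steps, centers clipped inside the epoch, no
  padding), gamma grid 40–100 Hz at 2.5 Hz, smoothing ±10 Hz
  (time-bandwidth = width × 10, i.e. 5 tapers at 0.3 s and the single-taper
  limit at 0.1 s). Power at arbitrary frequencies is computed by explicit
  complex-exponential projection, so the output grid need not coincide with
  the window's rfft bins.

## 3. Connectivity (`prepercept.connectivity`)

Coherence and imaginary coherency are the magnitude and imaginary part of
the trial/taper-averaged normalized cross-spectrum (single-estimate inputs
are rejected as degenerate). Directed influence is Geweke's spectral
Granger causality computed **nonparametrically**: the trial-averaged CSD is
factorized as `S(f) = H(f) Σ H(f)*` with Wilson's iterative spectral-matrix
factorization, and

    G_{y→x}(f) = ln( S_xx / (S_xx − (Σ_yy − Σ_xy²/Σ_xx) |H_xy|²) ),

clipped at zero (clipping is logged). Direction naming is fixed in one
place: feedback ≡ FFA→V1, feedforward ≡ V1→FFA.

Wilson iteration: initialization from the Cholesky factor of the
frequency-averaged S (the lag-0 autocovariance), update
`ψ ← ψ [ψ⁻¹ S ψ⁻* + I]_+`, stopping when the successive-iterate change
falls below 1e-9 **or** the reconstruction error `‖HΣH* − S‖/‖S‖` falls
below 1e-6 (checked every 10 iterations — near-singular small-sample CSDs
keep drifting at the grid's representation floor long after S is
reproduced); maximum 500 iterations. The reconstruction error is the
operative convergence criterion. A relative ridge of 1e-10 × mean diagonal
guards PSD failures of finite-sample estimates; `connectivity_spectrum`
retries once at doubled padding if the tolerance is not reached (needed for
condition CSDs with ≲ 25 trials). Granger consumers refuse non-converged
factorizations.

Validation is dual-route: `parametric_granger_var` evaluates the same
Geweke measure in closed form from the analytic VAR transfer function
`H(f) = (I − Σ_k A_k e^{−iωk})⁻¹`, and tests require the nonparametric
path to match it (at the oracle's peak, within 15 % at 500 trials, with
error decreasing in trial count). A regression test freezes the canonical
coupled VAR's peak value obtained by a third route (least-squares VAR fit
to a 2×10⁶-sample realization). The pole radius matters here: with sharply
resonant sources (radius ≳ 0.9) the Geweke peak becomes narrower than any
reasonable multitaper smoothing and the nonparametric estimate is biased
low by tens of percent — an estimator property, not an implementation
error; the default 0.8 keeps the peak wider than the ±2 Hz smoothing.

The **time-reversal control** reverses the samples *inside the analysis
window* (so the reversed analysis sees exactly the same data segment) and
reruns the identical pipeline; genuine lagged interactions flip direction,
and the tests require the feedback/feedforward dominance to flip in ≥ 95 %
of simulated subjects.

## 4. Decoding (`prepercept.decoding`)

Epochs are band-limited to 1–33 Hz (zero-phase FIR, 101 taps; the outer
~0.2 s of the epoch carries edge effects, which is why decoding statistics
are evaluated over 0–350 ms). Per time sample, features are z-normalized
with training-fold statistics only and a logistic regression classifier
(L2, C = 1, fixed — not tuned per fold, to keep runs deterministic) is
trained under seeded stratified fourfold cross-validation, the fold split
fixed across time points. AUC is computed from the pooled held-out decision
values (per-fold averaging available). The solver is an in-module damped
Newton iteration on exactly scikit-learn's objective (unit-tested to agree
with `LogisticRegression` to 1e-5), warm-started across neighboring time
samples for speed.

Fold-averaged weights are converted to activation patterns by the Haufe
transform `A = Cov·w` with the per-time channel covariance over all trials
(ridge 1e-6 × mean eigenvalue), unit-normalized with sign fixed so
`⟨A, w⟩ ≥ 0`. Patterns are projected into "source" space through a
(grid × channels) spatial filter — on synthetic data the pseudo-inverse of
the known mixing, declared as the stand-in for anatomical source
reconstruction — and ROIs are the grid points whose rectified,
window-averaged values reach 95 % of the maximum (ties kept; windows
50–120 ms and 120–200 ms by default).

## 5. Group statistics (`prepercept.stats`)

- **Cluster-based permutation test** (paired, within-subject): cell-wise
  paired t statistics thresholded at the cluster-forming α = 0.05 quantile
  (one- or two-sided as declared per contrast), connected supra-threshold
  cells summed (1-D adjacency: neighboring frequency bins; 2-D:
  4-connectivity, 8-connectivity switchable), null distribution from random
  within-subject condition swaps (sign flips of the paired differences)
  using the maximum |cluster sum|; `p = (exceedances + 1)/(n_perm + 1)`.
  Defaults: 1000 permutations; the decoding-significance test uses 10000 so
  its p floor of ~1e-4 matches the granularity the decoding contrast needs.
  Type-I calibration is verified by simulation (500 null experiments × 500
  permutations, rejection rate within [0.03, 0.07]).
- **Within-subject SEM**: Cousineau normalization (subject means removed,
  grand mean restored) with Morey's `sqrt(C/(C−1))` correction; verified
  against a hand-computed table.
- **Run-length analysis**: same-report run lengths binned as 0–10
  repetitions (top bin capped), averaged across subjects, fitted by least
  squares with a scaled Binomial(n = 10, p) mass (p on a fine grid, scale
  closed-form); `R² = 1 − SS_res/SS_tot`. The binomial parameterization is
  underdetermined in the source analysis; fixing n at the bin cap and
  freeing p is this package's declared choice. The `stochastic` flag
  additionally requires `p̂ < 0.5`, because a perseverating reporter's
  top-bin histogram is fit perfectly by a p ≈ 1 binomial.
- **Correlations**: Pearson r with the t-transform p and Fisher-z 95 % CI.

## 6. Pipeline (`prepercept.pipeline`)

`run_pipeline` executes: simulate → (optional) per-subject decoding with
ROI extraction and the group decoding-vs-chance cluster test (one-sided,
0–350 ms) → pseudo-inverse source reconstruction → time-frequency contrasts
in both nodes (two-sided; both window widths) → prestimulus power contrasts
(two-sided, 5–25 Hz) → coherence and |imaginary coherency| contrasts
(one-sided, face > vase) → feedforward and feedback Granger contrasts
(one-sided) → the same Granger contrasts on time-reversed data → per-subject
maxima (peak AUC over 0–350 ms; peak face−vase gamma effect from the 300-ms
window; peak feedback Granger over 5–25 Hz, conditions averaged) → the
three cross-subject correlations. Every group result records its settings
and contributing subjects; `summary.json` carries the config hash and
seeds, and rerunning with the same config is byte-identical.

The time-frequency contrast defaults to **induced power**: the
per-condition evoked mean is subtracted per subject before the
transform. Without this, the large face-trial evoked transients splatter
broadband power into analysis windows that truncate them (a window-edge
discontinuity effect) and produce spurious gamma-range clusters in the
V1-like node at full cohort size; subtracting the ERP removes the
deterministic transient while leaving the random-phase gamma burst intact.
Each condition's mean power is rescaled by `n_c/(n_c − 1)` to undo the
1/n stochastic-power loss of the mean subtraction, so unequal per-condition
trial counts cannot bias the contrast.

Two further analysis-window rules keep the post-stimulus contrast honest:
the cluster statistics use only analysis windows lying *fully* after
stimulus onset (center ≥ onset + width/2). Windows straddling t = 0 mix in
prestimulus samples, where the conditions differ by construction (the
coupling), and at full cohort size that contamination shows up as spurious
"post-stimulus" V1 clusters. The full-epoch time-frequency maps are still
computed and returned — only the statistics window is restricted. Even so,
a small residual V1 detection excess (~10 % of cohorts vs ~7 % under a null
generator, statistically compatible) remains at the declared effect sizes;
it is listed under limitations.

Statistical testing of connectivity is restricted to 5–25 Hz because the
generated (and, in the emulated study, observed) prestimulus oscillatory
power is concentrated there — frequency-domain connectivity measures are
only interpretable where there is oscillatory power. The imaginary-coherency
contrast uses |imag coherency| since its sign merely encodes lead/lag
direction.

## 7. Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at sizes chosen to
make every property measurable on a single desktop CPU: oracle equivalence
at 500 trials × 1 s; direction recovery and time reversal over 100
simulated subjects × 120 trials; cluster-test calibration over 500 null
experiments × 500 permutations (20 subjects, 21 frequency bins); the double
dissociation over 20 effect cohorts and 8 burst-off cohorts of 20 subjects
× 120 trials; one fully featured cohort (decoding included) of 20 subjects
× 150 trials. The generator's scientific defaults (`n_trials = 400`) are
unchanged by these choices — repeated-cohort runs simply use fewer trials
per subject, at which size every intended effect is still detected
essentially always.

## 8. Known limitations

- Bivariate only: no conditional (multi-node) Granger, no PDC/DTF, no
  phase-slope index.
- The pseudo-inverse spatial filter is exact for the simulated forward
  model; real inverse operators introduce leakage the synthetic tests do
  not probe. Correlated reconstruction noise plus genuine unidirectional
  coupling produces a small spurious reverse-direction Granger component —
  visible here as occasional weak feedforward contrasts at large cohort
  sizes, and exactly the failure mode the time-reversal control exists to
  catch.
- Power contrasts on skewed single-trial power with unequal per-condition
  trial counts can be mildly miscalibrated at the margins; the pipeline's
  contrasts operate on trial-averaged (near-Gaussian) per-subject maps
  where this effect is small.
- The run-length binomial fit is a descriptive goodness-of-fit device, not
  a generative model of perceptual sequences.
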