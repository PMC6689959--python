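# prepercept

Analysis toolkit for a question in bistable perception: does the brain's
state *before* an ambiguous stimulus appears bias *what* is subsequently
perceived? Concretely, for a briefly flashed Rubin face/vase picture, does
prestimulus feedback connectivity from a category-sensitive region (FFA)
to early visual cortex (V1) in the alpha band predict whether the observer
reports faces or a vase?

The package is aimed at researchers analyzing trial-epoched
electrophysiological recordings (MEG/EEG source time courses) and at anyone
who wants a fully validated, ground-truth-tested implementation of the
analysis chain:

- **behavior** — run-length analysis of report sequences with a binomial
  goodness-of-fit (is the trial-by-trial report stochastic?);
- **decoding** — sample-by-sample logistic-regression decoding of the
  reported category (AUC), activation-pattern (Haufe) transformation of the
  classifier weights, projection into source space and 95 %-of-maximum ROI
  extraction;
- **spectral** — multitaper (DPSS) cross-spectral densities and
  sliding-window time-frequency power, including the analysis-window
  smearing control;
- **connectivity** — coherence, imaginary coherency, and nonparametric
  spectral Granger causality via Wilson's spectral-matrix factorization
  `S(f) = H(f) Σ H(f)*`, with Geweke's directed measure
  `G_{y→x}(f) = ln S_xx / (S_xx − (Σ_yy − Σ²_xy/Σ_xx)|H_xy|²)`, a
  closed-form parametric oracle, and the time-reversal control;
- **stats** — cluster-based permutation tests over frequency and
  time-frequency grids, within-subject (Cousineau–Morey) SEM, and
  cross-subject Pearson correlations of per-subject maxima;
- **simulate** — a synthetic 20-subject cohort generator (bivariate VAR
  sources with condition-dependent prestimulus FFA→V1 coupling, a
  post-stimulus gamma burst and evoked responses on face trials, linear
  sensor mixing, stochastic reports) whose known ground truth is what every
  other module is validated against.

Because the original recordings are not publicly available, the package's
validity argument is built entirely on parameter recovery: the directed
coupling planted by the generator must be recovered by the estimators, in
the right direction, at the right frequencies, with calibrated statistics
— and must vanish under time reversal and under null configurations.

## Worked example

```python
import numpy as np
from prepercept.pipeline import PipelineConfig, run_pipeline
from prepercept.simulate import SimulationConfig

cfg = PipelineConfig(
    simulation=SimulationConfig(n_subjects=8, n_trials=100, seed=1),
    run_decoding=False,   # connectivity-only run; decoding adds ~10 s/subject
    n_perm=200,
)
bundle = run_pipeline(cfg, out_dir="results/demo")
print("face reports (%):", round(bundle.behavior["face_report_pct_mean"], 2))
print("run-length binomial R^2:", round(bundle.behavior["binomial_fit_r2"], 3))
print("feedback Granger cluster p:", bundle.granger_tests["feedback"].min_p)
print("feedforward cluster p:", bundle.granger_tests["feedforward"].min_p)
print("reversed feedback p:", bundle.granger_reversed_tests["feedback"].min_p)
print("FFA gamma cluster p:", bundle.tfr_tests["FFA_300ms"].min_p)
print("V1 gamma cluster p:", bundle.tfr_tests["V1_300ms"].min_p)
```

Output of this exact run:

```
face reports (%): 49.25
run-length binomial R^2: 0.968
feedback Granger cluster p: 0.004975124378109453
feedforward cluster p: 1.0
reversed feedback p: 1.0
FFA gamma cluster p: 0.009950248756218905
V1 gamma cluster p: 0.3383084577114428
```

Reading it: reports are at chance and stochastic trial-to-trial (binomial
R² ≈ 0.97); the prestimulus face-vs-vase contrast is significant for
feedback (FFA→V1) Granger causality but not feedforward; on time-reversed
data the feedback effect disappears (it reappears in the feedforward
direction, confirming a genuine lagged interaction); and the post-stimulus
gamma-band contrast is significant in the FFA-like node only. That is the
full qualitative fingerprint the generator plants.

The same stages are scriptable from the shell:

```bash
prepercept simulate --config study.cfg --out cohort/ --seed 7
prepercept decode --epochs cohort/s00.h5 --folds 4 --band 1 33 --seed 0 --out dec.h5
prepercept connectivity --epochs cohort/s00.h5 --window -1.0 0.0 --band 5 25 --out conn.csv
prepercept run --config study.cfg --out results/
```

where `study.cfg` is flat `key = value` text (`prepercept --help` and the
`prepercept.cli` docstring document the schema).

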