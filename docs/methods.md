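# Methods

## The analysis model

`connmed` estimates whether a behavioural trait X (psychological
resilience) relates to a cognitive outcome Y (processing speed) through
the intrinsic functional connectivity of a brain region M.  Connectivity
is summarised per subject by weighted degree centrality:

    dc(N_i) = sum_{j != i} x_ij

where x_ij are the positive Fisher-z edge weights of a sparsity-thresholded
network.  Associations are partial Spearman correlations controlling age,
sex and education; inference on the mediated path uses the standard
three-regression model

    M = i1 + a X + covariates
    Y = i2 + c' X + b M + covariates
    Y = i3 + c X + covariates

with the indirect effect a·b and a bias-corrected bootstrap CI.  All three
regressions share one covariate set, so c = c' + a·b holds to machine
precision and is asserted on every fit.

## Preprocessing assumptions and choices

* **Framewise displacement.**  The motion-exclusion and scrubbing
  thresholds in this literature (0.2 mm mean, 0.5 mm per volume) are tied
  to the Power convention, so FD is the L1 norm of the six back-differenced
  rigid-body parameters with rotations converted to arc length on a 50 mm
  sphere.  FD is a per-volume quantity; only that reading makes the
  neighbour-censoring rule ({t−1, t, t+1, t+2} around an exceedance)
  coherent.
* **Scrubbing as regressors.**  Flagged volumes are censored with one
  unit-impulse nuisance column each, inside the same regression as the
  tissue/global signals and the Friston-24 expansion — not by row
  deletion, which would break the fixed-length time axis the band-pass
  filter needs.
* **Cleaning order** is fixed: discard → FD/spikes → joint nuisance
  regression → band-pass.  Whether tissue signals should themselves be
  filtered before regression is not settled practice; regressing first and
  filtering last keeps the residual series orthogonal to the unfiltered
  confounds and is what the test suite asserts.  A 100-seed simulation
  confirms the chain leaves correlation estimates of independent white
  noise unbiased (mean off-diagonal r within ±0.02 of 0).
* **Band-pass** is a 4th-order Butterworth (0.01–0.1 Hz) applied
  forward-backward (`sosfiltfilt`), i.e. zero-phase with a squared
  magnitude response.  At TR = 2 s this passes a 0.05 Hz probe within 10%
  and attenuates a 0.2 Hz probe by far more than 90%.
* **Motion QC rule.**  The inclusion wording "≤ 2 mm and ≤ 2°, or mean
  FD ≤ 0.2 mm" is ambiguous; the default is the conservative conjunction
  of all three bounds, with `motion_rule="disjunction"` available for the
  alternative reading.  All bounds are inclusive.

## Network and metric conventions

* Edge retention at sparsity S keeps k = round(S·n(n−1)/2) edges
  (round-half-away-from-zero), drawing only from strictly positive
  Fisher-z values; ties at the cut break by ascending (i, j) index for
  reproducibility.  Weights are never binarised or modified.
* Since atanh is monotone, thresholding z-values and thresholding raw
  correlations select identical edge sets (asserted in tests).
* Nodal efficiency and betweenness use the standard weighted conventions:
  edge length 1/x_ij, efficiency normalised by n−1 with unreachable pairs
  contributing zero, betweenness unnormalised with equal-length paths
  split fractionally.  Metric vectors are averaged over the 10-threshold
  sweep (plain mean), then left/right homologue ROIs are averaged into one
  regional value; both operations are linear so their order is immaterial.

## Statistical estimators

* **Partial Spearman** = rank every variable (average ranks on ties),
  residualise the x- and y-ranks on [intercept | covariate ranks],
  Pearson-correlate the residuals; p from the t approximation with
  n − 2 − #covariates degrees of freedom, two-sided.  With one covariate
  this equals the first-order recursive partial-correlation formula (the
  test oracle); with none it is exactly ordinary Spearman.  Sex enters as
  a 0/1 code; ranking preserves the grouping.
* **Permutation test** shuffles the outcome only, keeping predictor and
  covariate rows aligned, and uses the add-one empirical p-value so p is
  never zero.  Calibration at n = 101 with three covariates: rejection
  rate 0.048 at α = 0.05 over 500 replicates.
* **FDR** is Benjamini–Hochberg step-up across exactly the screened
  regions (statsmodels backend, verified against a hand-rolled step-up
  oracle and against worked four-region examples).
* **Mediation** bootstrap resamples subjects (cases, not residuals); a
  resample with a rank-deficient design is redrawn and counted, and more
  than 10% degenerate draws aborts.  The CI is bias-corrected (BC, not
  BCa): z0 = Φ⁻¹(fraction of draws below the point estimate), endpoints at
  the Φ(2z0 ± z_{α/2}) quantiles.  Paths are reported standardised
  (z-scored x, m, y) by default because indirect effects in this
  literature are printed on that scale; `standardize=False` gives raw
  units.  Covariates appear in both the mediator and outcome equations.
  When education itself is the mediator it is dropped from the covariate
  set (age and sex remain).

## The synthetic cohort

The generator emulates a 101-subject ageing cohort (90 ROIs, 240 volumes
at TR = 2 s, ages 60–79, ~72% female) whose ground truth is known:

* Resilience ~ truncated Normal(28.4, 5.63²) on [0, 45]; education ~
  truncated Normal(12.2, 4.67²) ≥ 0; processing speed is mapped to mean
  53.9, SD 10.7 and rounded to a non-negative integer.  MoCA and GDS are
  drawn inside the inclusion ranges because the emulated cohort is
  post-screening; motion QC can still exclude subjects.
* A latent u = path_a·z(resilience) + noise (path_a = −0.55, noise SD 0.8)
  scales all covariance entries touching the target region's two ROIs by
  (1 + 0.9·tanh(0.4·u/0.9)) — a smooth squash rather than a hard clip, so
  the connectivity response to the latent has no kink.  Planting the
  effect in the covariance (not as added signal) makes the population
  degree of the target analytically computable from the exact matrix, and
  monotone in the modulation.
* The base covariance is single-factor: entry (i,j) = l_i·l_j with
  loadings drawn once per cohort from U(0.45, 0.75).  This gives the broad
  edge-strength distribution of empirical connectivity matrices, so
  sparsity thresholds retain a stable core of strong edges instead of
  breaking ties among identical ones.  An exchangeable scalar base remains
  available and is what the arithmetic examples use.
* Speed = path_b·u + path_c_prime·z(resilience) + covariate effects
  (age −0.5, education +0.3, sex 0, standardised) + noise (SD 0.75), with
  path_b = −0.55.  Signs follow the phenomenon being emulated: higher
  resilience → lower target-region centrality, lower centrality → faster
  speed, hence a positive indirect effect.
* ROI series are stationary AR(1) (φ = 0.2) with the modulated matrix as
  innovation covariance, plus a shared low-frequency global signal
  (coupling 0.2) that the nuisance regression must remove; motion is a
  Gaussian random walk with occasional persistent step displacements
  (0.6–1.0 mm, probability 0.005/volume) so each spike yields exactly one
  FD exceedance.

**Mediator reliability and the planted direct path.**  At 235 band-passed
volumes the threshold-averaged bilateral degree correlates ~0.89 with the
latent it measures; this is a property of scan length, not of the
implementation.  Classical errors-in-variables attenuation therefore moves
roughly 0.10 (standardised) of the latent-mediated association into the
fitted direct path.  Because the cohort is meant to emulate a study whose
*observed* pattern is full mediation (significant indirect, nonsignificant
direct), the default planted direct path is −0.11: it offsets the expected
attenuation bias so the fitted direct effect is centred on zero.  Setting
`path_c_prime = 0` instead yields a cohort whose fitted direct effect is
systematically positive — worth knowing when designing power studies with
this generator.

**What passing tests do and do not show.**  The generator's networks are
stationary Gaussian with a one-factor base and a single modulated region;
real fMRI has non-Gaussian noise, distance-dependent artefacts,
physiological rhythms, and many correlated effects.  Recovery of the
planted mediation here demonstrates that the pipeline's statistics are
correct and calibrated, not that any real-data effect of this size would
be detected.

## Problem sizes used in validation

Chosen to give stable Monte-Carlo estimates at interactive runtimes:
permutation calibration uses 500 replicates × B = 1000; mediation
recovery/type-I use 200 replicates each (n = 1000 planted, n = 101 null,
1000 bootstrap draws); the end-to-end replication runs 25 master seeds of
the full 101 × 90 × 240 study (significant in ≥ 23), and the null-cohort
check 50 replicates (significant in ≤ 5).  Exhaustive betweenness
enumeration is limited to graphs of ≤ 7 nodes; larger graphs are checked
against an independent Dijkstra-based solver.

## Determinism

Every stochastic routine takes a seed; the pipeline derives stage seeds
from one master seed via `numpy.random.SeedSequence.spawn`, so a config
plus seed reproduces every output table byte for byte (asserted in tests).

## Known limitations

* Single-mediator models only; no moderated mediation or alternative
  causal orderings beyond the education-mediator variant.
* No voxel-level processing: the pipeline starts from extracted ROI time
  series and text-format motion parameters.
* Negative edges are discarded (positive-weighted networks); no
  absolute-value or signed-network variants.
* The BC interval is bias-corrected but not accelerated (no jackknife
  acceleration term).
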