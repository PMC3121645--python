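# Methods

## The statistical model

Each observation of a bi-allelic marker on a tetraploid sample is a pair of
non-negative channel intensities `(s_a, s_b)`. We analyze the allele signal
ratio `f = s_a / (s_a + s_b)` after the arcsine-square-root transform
`y = asr(f) = arcsin(sqrt(f))`, which maps [0, 1] onto [0, pi/2] and
stabilizes the variance of fractions near the boundaries. Records with
`s_a + s_b = 0` carry no ratio information and are dropped (counted, never
silently).

On the transformed scale we fit a five-component normal mixture

    p(y) = sum_{x=0..4} pi_x * N(y; mu_x, sigma),

one component per allele-a dosage `x` (nulliplex to quadruplex), with a
common standard deviation `sigma`. Two groups of constraints make the
model identifiable and automatically tie components to dosage classes:

**Mean constraints.** Assuming the expected channel signals respond
(at most quadratically) to dosage,

    E(s_a) ~ c1 + x + d x^2
    E(s_b) ~ c2 + r (4 - x) + r d (4 - x)^2,

the expected fraction, after absorbing the overall signal scale, is

    mu_x = asr( (c1 + x + d x^2) / (c1 + x + d x^2 + c2 + r (4-x) + r d (4-x)^2) ).

Here `c1, c2 >= 0` are channel backgrounds relative to the a-channel
sensitivity, `r > 0` is the b:a sensitivity ratio and `d >= 0` a relative
curvature shared by both channels (the b-channel curvature term is scaled
by `r`; the alternative placement without the `r` factor is the one
genuinely ambiguous reading of the quadratic extension — we use the
"equal relative curvature" form and keep it isolated in
`model.mean_model_eval`). Four nested variants are fitted: model 1
(`c1, c2, r`), model 2 (`c = c1 = c2, r`), model 3 (`c1, c2, r, d`) and
model 4 (`c, r, d`). For any admissible parameters the five means are
strictly increasing in dosage, so component `x` *is* dosage `x` — no
post-hoc cluster-to-genotype matching is needed.

**Mixing-proportion constraints.** Either the four free proportions are
estimated, or the five proportions are constrained to Hardy-Weinberg
ratios `pi = (p^4, 4p^3q, 6p^2q^2, 4pq^3, q^4)`, `q = 1 - p`, driven by a
single allele frequency. Convention: `p` is the frequency of the **b**
allele, so `pi_0 = p^4` is the probability of the nulliplex-a class; output
tables report both `p` and `p_allele_a = 1 - p`. The HWE restriction often
stabilizes peak identification even when the population deviates somewhat
from equilibrium.

Model complexity is scored by `BIC = -2 LL + k ln(n)`, where `k` counts the
mean parameters (3/2/4/3 for models 1-4) plus 1 for `sigma` plus 4 (free)
or 1 (HWE) for the proportions.

Two known approximations are inherited from the modelling choice: the model
describes `asr(E(s_a)/(E(s_a)+E(s_b)))` while the data are
`asr(s_a/(s_a+s_b))` per sample (fraction-of-expectations vs.
expectation-of-fraction, plus transformation bias). Both are small for
tight peaks; the simulator's raw-signal noise mode exists to probe them.

## EM fitting

Each variant is fitted by expectation-maximization:

- **E-step**: posterior membership probabilities, computed in log space
  with log-sum-exp normalization; rows whose density underflows entirely
  fall back to the prior.
- **M-step, proportions**: free — column means of the posterior matrix;
  HWE — the closed-form dosage-weighted binomial MLE
  `p_hat = sum_ij post_ij (4 - x_j) / (4n)` (exact for this constraint).
- **M-step, means and sigma**: minimize the weighted least-squares
  criterion `sum_ij post_ij (y_i - mu_x(theta))^2` over the mean
  parameters, warm-started from the current values, with bounds
  `c1, c2 >= 0`, `r > 0`, `d >= 0` (trust-region reflective
  `scipy.optimize.least_squares`). The double sum is collapsed exactly to
  five residuals `sqrt(W_x) (ybar_x - mu_x(theta))` plus a
  parameter-independent within-class term (`W_x` = posterior column mass,
  `ybar_x` = weighted class mean), which makes each M-step O(n) + a
  5-residual NLS. `sigma^2` is the minimized weighted RSS over `n`.

Numerical choices (the underlying method statement is silent on all of
these, so they are this package's own):

- convergence when `|delta LL| < 1e-6`, cap 500 iterations;
- `sigma` floored at `1e-4` (transformed scale) to prevent spike
  components;
- `sigma` initialized as the pooled within-group SD of the hard assignment
  of observations to the nearest start mean;
- start parameters obtained by unweighted least-squares projection of the
  five start means onto the mean model; proportions start uniform (free)
  or at `p = 0.5` (HWE);
- all-identical observations raise a fit failure (a five-component mixture
  is meaningless there); the pipeline records the failure and moves on;
- no random numbers anywhere in fitting: both start configurations are
  deterministic functions of the data, so repeated runs are bit-identical.

Two start configurations are used per variant: (1) complete-linkage
hierarchical clustering of `y` cut at five groups (group means sorted;
degenerate/duplicate groups padded by widest-gap midpoints; an all-equal
result falls back to the grid), and (2) five equidistant values on the
transformed scale from `asr(0.02) = 0.142` to `asr(0.98) = 1.429`.

## Per-marker selection procedure

1. **Intensity pre-filter** (raw two-channel input only): drop
   observations with Euclidean total intensity `sqrt(s_a^2 + s_b^2)` below
   3200 (GoldenGate-calibrated default, exposed as an option; at-threshold
   observations are retained). The marker is rejected
   (`low_intensity_coverage`) if fewer than 60% of its samples pass or
   fewer than 10 usable samples remain. Ratio-only input skips this step
   with a logged notice.
2. **16 fits**: 4 mean models x {HWE, free} x 2 starts. Individual
   numerical failures are recorded, not fatal; if every fit fails the
   marker is rejected (`all_fits_failed`).
3. **Provisional selection** by minimum BIC (ties broken by model id
   ascending, HWE before free, then start order).
4. **Gap-misfit rescue**: when channel sensitivities are strongly unequal
   (`r` far from 1) a wide empty interval separates the nulliplex or
   quadruplex peak from its neighbour, and EM sometimes strands the
   simplex or triplex component inside it. Detection: the dosage-3
   component has lower mixing proportion *or* fewer provisionally assigned
   samples than both neighbours (`triplex_in_gap`; checked first), or
   analogously dosage 1 (`simplex_in_gap`). If detected, the 8 variants
   are refitted once from a rearranged start: for a triplex misfit the
   duplex/simplex/nulliplex means move up one slot and the new nulliplex
   mean is halfway between the new simplex mean and 0; the simplex case is
   the mirror construction toward pi/2 (our symmetric reading, isolated in
   `pipeline.rescue_start_means`).
5. **Valley rejection**: a fitted solution with an interior dosage class
   that has fewer assigned samples than at least one class on each side is
   not expected in a cross progeny or an HWE population; such fits are
   removed — unless every fit is flagged, or the check is disabled, in
   which case none are removed. Evaluated on assigned-sample counts (what
   a population actually constrains); run once over the union of all
   completed fits, after any rescue round.
6. **Final selection** by minimum BIC among survivors; **genotype
   assignment**: a sample is called with its argmax dosage only if the
   maximum posterior exceeds 0.99 (default).
7. **Marker QC**, each rejected marker carrying exactly one reason, checked
   in this order: call fraction < 60% (`low_call_fraction`); fitted
   `sigma` > 0.1 on the transformed scale (`sigma_too_high`); more than
   85% of *assigned* samples in one class (`one_peak_dominant`).

### Tunable thresholds (defaults)

| option | default | meaning |
|---|---|---|
| `intensity_threshold` | 3200 (raw units) | minimum total intensity per observation |
| `min_samples_above_threshold_fraction` | 0.60 | marker-level intensity coverage |
| `call_prob_threshold` | 0.99 | posterior needed to assign a dosage |
| `min_call_fraction` | 0.60 | minimum fraction of called samples |
| `max_sigma` | 0.1 (transformed scale) | maximum component SD |
| `max_peak_fraction` | 0.85 | maximum share of assigned samples in one class |
| `valley_check_enabled` | on | reject lower-peak-between-higher-peaks fits |

`call_prob_threshold` and `min_call_fraction` interact (stricter calling
lowers the call fraction); `max_sigma` can be lowered for low-noise assays
and `max_peak_fraction` raised for larger panels. Trying a few settings on
a marker subset and inspecting the plots before a full run is recommended.

## The simulator

`simulate.SimulationConfig` / `simulate_marker` / `simulate_panel` generate
panels with known truth. Defaults emulate a well-behaved 224-sample
GoldenGate-style marker: dosages drawn from HWE proportions, noise SD 0.04
on the transformed scale, total intensity log-normal with mean 8000 and
CV 0.3 (only its ratio to the 3200 threshold matters downstream).

Two noise modes: `transformed` adds Gaussian noise directly on the scale
the model fits (making parameter-recovery tests sharp — the fitted model is
exactly true); `raw` applies multiplicative log-normal noise (CV = `sigma`)
to each channel's expected signal, which reintroduces the two approximations
above and the natural skew of ratios near the boundaries.

Planted failure modes:

- `monomorphic`: every sample is quadruplex. Noise is drawn in raw mode
  regardless of the configured mode: additive transformed-scale noise on a
  boundary class (mean near asr(0.995)) would clip at pi/2 and create an
  artificial skewed atom no real assay shows, whereas channel-level noise
  yields the realistic tight boundary cluster. Expected outcome:
  `one_peak_dominant`.
- `diffuse`: noise SD 0.25, far above the 0.1 QC cap. Expected outcome:
  `sigma_too_high` or, since few posteriors clear 0.99, `low_call_fraction`.
- `wide_gap`: model 1 with `r = 5`, backgrounds 0.02, b-allele frequency
  0.1 and noise SD 0.03 — a well-performing (tight-peak) assay whose only
  pathology is the unequal channel sensitivity. The quadruplex peak sits
  far from the four closely spaced lower peaks and the low-dosage classes
  are nearly empty, the regime in which EM strands a component in the gap;
  this exercises the rescue step, which should recover a correct fit.
- `low_intensity_fraction`: the chosen fraction of observations is rescaled
  below the intensity threshold, exercising the pre-filter.

What passing on simulated data does **not** show: the transformed-mode
generator matches the fitted model exactly, so recovery results there are
an upper bound on real-data behaviour; real assays add batch effects,
allele-specific amplification artifacts, null alleles (invisible alleles
that shift ratios off-class — explicitly out of scope for detection here)
and non-Gaussian outliers none of which are simulated. The raw-noise mode
covers only the transform-approximation part of that gap.

## Problem sizes

The test suite and `scripts/acceptance.py` use panels of up to 26 markers x
224 samples, recovery sweeps of 8 variants x 10-25 replicates at n = 500,
50 random mixtures for EM monotonicity, and n = 30 toys for the grid-search
likelihood oracle — sizes chosen so a complete verification run finishes in
a few minutes on one core while keeping every per-marker statistic at the
224-sample scale the method targets.

## Known limitations

- Exact numeric identity with other implementations of the same procedure
  is not expected: convergence rule, sigma floor and clustering linkage are
  deliberate choices of this package, and per-fit likelihoods depend on
  them (selection outcomes are far less sensitive).
- The quadratic-curvature placement in the b channel (`r d` vs `d`) is an
  interpretation; both readings coincide at `d = 0` and differ little for
  small `d`.
- Null alleles are not detected or modelled.
- Markers with fewer than 10 usable samples are never fitted.
- The gap-misfit rescue runs one round only and tests the triplex side
  first; pathological fits that misplace both simplex and triplex would
  need the valley filter to catch them.
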