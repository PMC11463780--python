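# Methods

## Model

Melting curves are modelled per identifier (protein, gene or peptide group)
as latent functions under a hierarchical Gaussian process.  In the
three-level hierarchy a protein-wide trend `h` has a zero-mean GP prior,
each condition's curve `g_c` is a GP centred on `h`, each replicate's curve
`f_cr` is a GP centred on its condition's `g_c`, and observations add i.i.d.
Gaussian noise with variance `beta^2`.  All kernels are RBF,
`k(t,t'|lambda) = exp(-|t-t'|^2 / 2 lambda^2)`; `h` and `g` share the
lengthscale `lambda_1`, replicates use `lambda_2`.  The four-level variant
inserts peptide-level curves between condition and replicate (lengthscale
`lambda_3` for the replicate level), which serves peptide-resolved data
where peptide groups — e.g. phosphorylation patterns — play the role of
conditions.

Because the hierarchy is linear in the latent functions, marginalising them
gives `Y ~ N(0, Sigma + beta^2 I)` with, for the three-level model,

    Sigma[(c,r,t),(c',r',t')] = sigma_h^2 k(t,t'|l1)
                              + 1[same g-group] sigma_g^2 k(t,t'|l1)
                              + 1[c=c', r=r'] sigma_fcr^2 k(t,t'|l2).

"Same g-group" is `c = c'` in the full model M1; a joint model M0 merges a
set of conditions into one group, leaving every other block untouched.  On
a synchronous temperature grid Sigma is a Kronecker product of per-level
index kernels with RBF correlation matrices; the dense elementwise formula
is the definition and also covers asynchronous designs (replicates need not
share a grid; missing observations are simply absent, never imputed).

With a single condition the protein and condition kernels coincide, so
`sigma_h^2` is pinned to zero there (identifiability).

## Scaling and centring

Raw intensities are divided by a per-replicate scalar: the lowest-
temperature reading (fold change) or the across-temperature mean (mean
scaling, the default for fitting — it is robust to a corrupted reading at
any single temperature and lets curves start at different values).
Replicate-divergence diagnostics (median and variance of per-temperature
between-replicate differences, lowest temperature excluded so the two
scalings are comparable) quantify the reproducibility gain.

The GP prior mean is zero while mean-scaled data sit near one, so
observations are centred by subtracting the per-identifier mean of the
scaled values before fitting; the offset is restored for prediction and
effect sizes.

## Fitting

Hyperparameters are estimated per identifier by type-II maximum likelihood:
L-BFGS-B on log-transformed parameters with analytic gradients (the
marginal covariance is linear in every output-scale), 3 seeded random
restarts, at most 1000 iterations, relative tolerance 1e-8.  Restart
initialisations draw lengthscales log-uniformly over their bounds and
output-scales log-uniformly in [1e-2, 1] times the data variance, with
`beta^2` near 10% of the data variance.  Bounds: lengthscales in [smallest
observed temperature spacing, 4 x observed range]; `beta^2 >= 1e-6`;
output-scales in [exp(-7), exp(8)] ~ [9e-4, 3e3] squared scaled-abundance
units.

The output-scale floor deserves a note: an unconstrained fit on null-like
data collapses `sigma_g^2` to numerical zero, which makes the test
statistic (below) a machine-precision-scale quantity whose sampled null is
not meaningfully ordered.  The floor keeps the statistic continuous; it
sits roughly two orders of magnitude below typical condition-level signal
on mean-scaled data and was verified not to affect the tails of the null
distribution.  Per-identifier seeds are derived from the run seed and a
CRC of the identifier, so parallel execution order cannot change results.

## Testing

For a comparison of conditions *a* and *b*,

    Lambda = -2 log [ p(Y | theta_hat, M0^{a,b}) / p(Y | theta_hat, M1) ]

with `theta_hat` the full-model fit used for both densities — a single fit
per identifier serves every comparison.  An equivalent conditional form
evaluates the ratio of the two conditional densities of the compared
conditions' observations given all non-compared conditions (dimension
N_a + N_b), cheaper with many conditions; both forms agree because the
marginal of the non-compared conditions is identical under M0 and M1.

Lambda's null distribution is approximated by sampling: draw observation
vectors from N(0, Sigma_M0 + beta^2 I), centre each draw, re-fit the full
model to it by the same type-II MLE procedure, and evaluate Lambda at the
draw's own estimates.  The re-fit is what makes observed and sampled values
exchangeable under the null — a draw scored at the observed `theta_hat`
(available as `refit=False`) is strongly anti-conservative, because the
observed fit adapted `sigma_g^2` to the data while the draw did not.  Null
re-fits are warm-started at the draw-generating parameters with a single
optimisation (tolerance 1e-6); pools produced this way are statistically
indistinguishable from pools of full multi-restart re-fits at a fraction of
the cost.

Three draw-source parameterisations of the joint model are available:

* `full_fit` (default): the full-model `theta_hat` plugged into the merged
  structure.  Under true signal its `sigma_g^2` inflates only the shared
  curve, so power is preserved; on null data its plug-in estimates make the
  empirical p-values mildly anti-conservative (measured type-I error ~0.1
  at nominal 0.05 on simulated nulls).
* `joint_fit`: the identifier's own joint-model MLE (classical parametric
  bootstrap).  Conservative under signal — the joint fit absorbs the
  condition difference into replicate scales, inflating that identifier's
  null — so it costs power.
* `group_pooled`: joint-model MLEs pooled across all identifiers sharing
  a design (same condition/replicate labels and temperature grids) —
  component-wise means for variance components (their MLE distributions
  are right-skewed, so medians undershoot badly), medians for lengthscales
  (robust to bound runaways).  With many identically-designed identifiers
  the pooled estimates are close to the truth and the p-values are
  calibrated (simulation: type-I error within the binomial band of 0.05,
  p-value uniformity not rejected); this is the recommended source for
  simulation studies and homogeneous designs, and the one used by the
  verification studies.

Null pools are per-identifier (independent pools, `per_id`) or shared
across a design group (`grouped`, much cheaper; p-values then co-move
through the shared pool, which inflates the variance of aggregate summaries
but not the level of individual tests).

Empirical p-values use the add-one convention `p = (1 + #{null >= obs}) /
(S + 1)` — strictly positive, exact under exchangeability, ties counted
conservatively.  BH adjustment is applied per comparison family.  Hits are
called either by `padj <= alpha` or by the stricter rule that the observed
Lambda exceeds every null sample (a tie counts against).

## Effect sizes and outlier flags

The signed Area Between the Curves integrates (treatment - control) over
the shared observed temperature range; the absolute ABC integrates the
absolute difference and stays large when stabilisation and destabilisation
cancel.  Two estimators: per-temperature medians of the scaled
observations (fast, outlier-sensitive), and posterior means of the
condition-level latent curves on a 301-point uniform grid (robust), both by
the trapezoidal rule.  Positive ABC means the treatment curve lies mostly
above the control curve.

Fitted replicate output-scales `sigma_fcr^2` measure how far a replicate
strays from its condition's trend; pooled across all identifiers, values
above the 95th percentile or above q75 + 1.5 IQR (linear-interpolation
percentiles, strict inequalities) flag outlier replicates.

## Synthetic data

The generator draws identifiers directly from the model: null identifiers
from the joint covariance (all conditions share one curve), differential
identifiers from the full covariance.  Default design: 2 conditions x 2
replicates x 10 temperatures (37-67 degC); generating values `lambda_1` =
15 degC, `lambda_2` = 8 degC, `sigma_h^2` = 0.05, `sigma_g^2` = 0.01,
`sigma_f^2` = 0.005, `beta^2` = 0.002 on the mean-scaled, centred scale,
chosen to produce realistic-looking melting curves.  Differential
identifiers use a condition-level scale of 0.05 (about seven times the
replicate-plus-noise residual scale): at these sample sizes weaker
separations are essentially undetectable and would make discovery-based
summaries vacuous.  `noise_multiplier` scales the correlated replicate-
level variance only.  Draws are emitted as `abundance = 1 + draw` and
consumed with scaling "none".

What the generator does *not* emulate: intensity-dependent and missing-
not-at-random measurement error, peptide-to-protein rollup artefacts,
batch effects, non-Gaussian heavy-tailed outliers (outlier studies inject
them explicitly), or between-protein parameter heterogeneity beyond what
fitting induces.  Passing calibration on these simulations therefore
demonstrates internal consistency of the statistical machinery, not
robustness to every failure mode of real MS data.

## Verification problem sizes

The studies behind `tests/test_acceptance.py` and `scripts/acceptance.py`
use: 200 random instances for the likelihood oracle; 200 000 draws for the
Monte-Carlo covariance check; 300 null identifiers with 500-sample
independent per-identifier pools for p-value calibration; 400 identifiers
(10% differential) with an 8000-sample grouped pool per noise level for FDR
control; 150 identifiers per noise level in {1, 10, 100} for ROC power;
500 identifiers (50 with an injected outlier) for the outlier mechanism;
100 identifiers for parameter recovery.  These are scaled-down analogues
of the full simulation study, sized so the whole suite completes on a
single CPU in well under half an hour.

## Numerical details

Cholesky factorisations add escalating jitter (1e-6 to 1e-3 of the mean
diagonal) before failing.  The three-level likelihood/gradient has a fused
fast path (direct LAPACK calls, contiguous replicate blocks) used by the
optimiser; it is bit-identical to the general path, which covers four-level
and non-contiguous designs.  Posterior variances are clipped at zero.
Integration grids are uniform with 301 points.  Percentiles use numpy's
linear interpolation.

## Known limitations

* Empirical p-values with `full_fit` draws are mildly anti-conservative;
  use `group_pooled` where designs repeat, or treat borderline calls with
  caution.
* The four-level model is fitted unconstrained; with many peptides and few
  replicates some output-scales are weakly identified.
* Lambda's scale depends on the observation count, so values are not
  comparable across identifiers with different designs — only p-values are.
* No positivity constraint on latent curves; predictions can dip below
  zero for steep melters (in practice prevented by the data).
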