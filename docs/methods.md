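# Methods

## The inference problem

A cell-scale signalling system is modelled as a sparse linear dynamical
system over N species concentrations x_t:

    x_{t+1} = A x_t + omega,        omega ~ N(0, sigma_sys^2 I)

The N x N transition matrix A is the network: `A[i, j] != 0` off the
diagonal means species j influences species i over the studied timescale.
Concentrations are not observed directly. Each assay pools several species
(antibody cross-reactivity), so an observation vector g_t of M << N entries
arises from a known pooling design Phi:

    g_t = Phi x_t + eps,            eps ~ N(0, sigma_meas^2 I)

Two empirical facts make this solvable by compressive sensing: between
adjacent time points only the few time-variant species change appreciably
(variations are sparse, a consequence of timescale separation), and each
pooled readout is a linear functional of the state. Initial concentrations
are assumed known.

## The sparse-Bayes engine

All sparse recoveries use automatic-relevance-determination (ARD)
regression: a Gaussian prior x_i ~ N(0, 1/alpha_i) per coefficient, the
Gaussian posterior

    Sigma = (diag(alpha) + sigma^-2 Phi'Phi)^-1,   mu = sigma^-2 Sigma Phi'g

and iterative re-estimation of alpha from the posterior moments. Two update
rules are provided: the variational rule `alpha_i = 1/(mu_i^2 + Sigma_ii)`
(slow, never prunes, very stable) and the MacKay relevance-vector rule
`alpha_i = gamma_i / mu_i^2` with `gamma_i = 1 - alpha_i Sigma_ii` (fast,
drives irrelevant precisions past the pruning threshold, default 1e12, which
fixes those weights at exactly zero). The default schedule is a hybrid:
variational iterations first (basin finding), then MacKay warm-started from
the reached hyperparameters (sparsification). Exact zeros matter: they are
what makes a structural call at threshold 0 meaningful.

Initial precisions default to a scale-equivariant value 1/s^2, where s is
the root-mean-square matched-filter coefficient `phi_j'g / phi_j'phi_j`; a
fixed starting precision is not scale-free and biases the EM basin when
concentrations are of order 100.

### Evidence-guided support refinement

With very few equations per unknown vector (the row regressions have only
P(T-1) = 8-28 equations against 300 columns) and strongly correlated
columns (concentration trajectories share ancestry; |corr| up to 0.99),
all EM-style ARD updates reliably converge to diffuse interpolating
supports even when a much sparser support has a far higher marginal
likelihood — exhaustive L0 enumeration shows the data identifies the true
support uniquely and the ARD evidence prefers it by 5-15 nats. The
estimator therefore finishes with a greedy local search over supports
(single-column deletions, additions and swaps; candidates prescreened by
the residual correlation of the column component orthogonal to the current
support), scoring each candidate by the exact ARD log marginal likelihood
with its hyperparameters re-optimized, from two independent starts (the EM
support and a greedy-forward build). When the winner still looks like an
interpolator (support size >= 4), the search restarts from the best
closed-form column pairs and, if needed, triples. A per-problem budget of
evidence evaluations (default 1000) and a minimum evidence gain per
accepted move (0.1 nat) bound the cost on low-information
problems. The refinement is enabled automatically for problems with at
most 64 equations, where this failure mode occurs; the large
concentration-recovery systems (M = 150) use the plain hybrid schedule,
which is accurate there. This is model selection under the method's own
objective, not a different estimator: the returned posterior is always the
standard ARD posterior on the selected support.

## The three steps

**Step 1 — concentration inference.** For each perturbation and each
adjacent pair of time points, the differenced system
`g_t - g_{t-1} = Phi (x_t - x_{t-1}) + noise` is solved by sparse Bayes
(the difference of two independent measurement noises doubles the noise
variance to 2 sigma_meas^2), and the variation estimates are accumulated
onto the known initial state. Covariances accumulate additively, treating
per-transition posteriors as independent; cross-time error correlation is
ignored, which understates late-time uncertainty slightly.

**Step 2 — network inference.** Each row a_i of A satisfies
`x_{t+1,i} = a_i' x_t`. All (perturbation, transition) pairs are stacked,
the Step-1 concentration means act as the design matrix, and each row is an
independent sparse recovery. The working noise variance is *not*
sigma_sys^2: the residuals carry propagated Step-1 estimation error, which
scales with the measurement noise and is amplified by sparse recovery and
accumulation. The default is `max(sigma_sys, 10 sigma_meas)`, clamped to
at most 10% and at least 1e-6 of the RMS concentration (the upper clamp
keeps heavy-noise runs informative, the lower one stays above
floating-point rounding for nominally noiseless inputs); it can be set
explicitly via `RunConfig.network_noise_std`.

**Step 3 — refinement.** The structural indicator calls a link where
`|A_hat[i, j]| > theta` (default theta = 0, relying on exact pruning);
diagonal entries are compared against the identity instead and never count
as links. Species with no off-diagonal call in their row or column are
*silent*: they are held at their known initial concentration, their pooled
contributions are subtracted from every observation, their design columns
are dropped, and measurements that pooled only silent species are removed.
On the reduced problem the variations are no longer sparse, so refined
concentrations come from conjugate Bayesian linear regression per time
point, with the Step-1 posterior as prior. Because Step-1 prunes variations
to exact zeros with zero variance, the prior diagonal receives a floor of
`2 sigma_meas^2 t` — pruning only certifies a variation below the
differenced noise level, and without the floor the prior is overconfident
and blocks the update. The reduced transition matrix is then re-inferred
row-wise by *extended* sparse Bayes, whose E-step replaces every product of
regressors by its expectation under the refined concentration posterior
(`<x x'> = <x><x>' + Cov(x)`), so concentration uncertainty enters the
expected second moments instead of being discarded. Note this expectation
acts as extra regularization: inflating the design covariance shrinks both
the posterior mean and its covariance. The benefit of Step 3 comes from the
problem reduction and the improved concentrations, not from the
expectation device alone.

## The synthetic benchmark

Six networks mirror well-studied pathway sizes through exact counts of
time-variant species and links (4/4, 11/20, 39/61, 50/83, 53/93, 58/101 in
300 species). The wiring is a seeded random *cascade-like* digraph: nodes
in a random cascade order, every node past the first receiving one edge
from an earlier node (weak connectivity), extra edges mostly feed-forward
with a 20% feedback minority, and in-degree capped at 3 — signalling
cascades integrate few upstream regulators while out-degrees may hub. Link
weights are uniform magnitudes in [0.2, 0.9] with random signs; the
interaction block is rescaled to spectral radius 0.95 if a draw exceeds
it. Time-invariant species keep identity rows; time-variant diagonals are
zero (regulator-determined dynamics — persistence diagonals were trialled
and discarded because a common decay mode on all-positive trajectories
degrades identifiability).

Baseline study conditions: 5 time points, 2-7 perturbations, initial
concentrations N(100, 20^2) truncated at zero and redrawn per perturbation,
system and measurement noise std 0.01 in absolute concentration units, and
150 pooled measurements from a regular LDPC-style binary design with
column weight 3 (every species in exactly 3 pools; row loads differ by at
most one; greedy load-balanced construction, deterministic per seed). The
noise-robustness sweep keeps the same benchmark and raises both noise
levels to 10, 5, 2, 1.

What the generator does *not* emulate: curated pathway wiring and
literature rate constants, nonlinear kinetics, non-Gaussian measurement
error, unequal antibody affinities (pool weights are exactly 1), and
unknown initial concentrations. Passing benchmarks therefore demonstrates
the inference machinery under the stated statistical shape, not biological
fidelity of any particular pathway.

## Evaluation

Link recovery is scored over all ordered species pairs excluding the
diagonal (self-dynamics are not interactions), with |A_hat| entries from
Step 2 as scores: trapezoidal AUROC and step-interpolated AUPR over the
full threshold sweep, plus sensitivity/specificity of the binary structure
at a fixed theta. Transition RMSE for Steps 2 and 3 is computed on the
same refined submatrix (rows and columns of the species kept active), so
the steps are compared on identical elements. The average posterior
variance over the refined matrix elements (pruned entries count as zero)
is the accuracy diagnostic; its log rank-correlates with the refined RMSE
across a grid, so it can stand in for the error when ground truth is
unavailable. Grids are run by `run_sweep`; the suite and the acceptance
script use a 2-network x 3-perturbation-count subgrid (n-11, n-39 at 3, 5,
7 perturbations, one seed) and 3 seeds for the hardest cell (n-58 at 2
perturbations) to keep wall-clock time in minutes while preserving the
quantities of interest.

## Numerical choices and degenerate inputs

Cholesky solves with a one-shot diagonal jitter retry (1e-10 trace/n);
the matrix-inversion lemma for the posterior when the active set exceeds
the number of equations; convergence when max |delta ln alpha| < 1e-6 over
the active set, capped at 500 iterations (cap hit returns
`converged=False` with a warning, never an exception). A fully zero design
is accepted as the no-information problem (the conjugate update returns
the prior); an all-zero *row* in a nonzero design is rejected. Zero
observations prune every coefficient immediately. All randomness flows
from explicit integer seeds through `numpy` seed sequences; end-to-end
runs are bit-reproducible from (inputs, config).

## Known limitations

- The Step-2 working-noise rule is a calibrated heuristic for error
  propagation; a full errors-in-variables treatment of Step 2 would
  estimate it jointly.
- Concentration covariance accumulation ignores cross-time correlation.
- The support search is a local optimizer with restarts; it inherits a
  (bounded) combinatorial cost on low-information problems and is gated
  off for large equation counts where EM alone suffices.
- Scores for ROC/PR come from a pruned estimate, so the ranking below the
  pruning level is not resolved; sensitivity at threshold 0 is the
  recall ceiling.
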