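# Methods

## Model and assumptions

The data summary is the allelic covariance matrix `omega_hat` between `N`
samples, computed from reference-allele frequencies at `L` unlinked biallelic
SNPs. Off the diagonal it is the mean over loci of
`(f_i - 1/2)(f_j - 1/2)`; the diagonal is the variance of a
randomized-reference allele indicator, exactly 1/4. The statistic does not
subtract locus means (so it is insensitive to sampling configuration) and is
invariant to which allele is called "reference" at each locus. For haploid
0/1 data it equals `(1 - 2 pi) / 4` exactly, with `pi` the pairwise mismatch
proportion.

The model treats allele-frequency deviations as independent across loci and
multivariate normal across samples, which makes `L * omega_hat`
Wishart-distributed with `L` degrees of freedom around the parametric
covariance

    Omega = gamma + sum_k w_k w_k' * G_k(D) + diag(eta),
    G_k(D) = alpha0_k exp(-(alphaD_k D)^alpha2_k) + phi_k.

Assumptions worth keeping in mind:

* *Unlinked loci.* Linkage disequilibrium reduces the effective degrees of
  freedom; the `df` argument of the estimator can be lowered to model this
  informally, but no estimator of the effective locus count is provided.
* *Geography is a proxy for connectivity.* Within-layer covariance decays
  with the supplied distances; if straight-line (or great-circle) distance
  misrepresents how the organism disperses (ring species, barriers), the
  spatial decay is misspecified.
* *The diagonal is conventional.* The observed diagonal is pinned at 1/4 by
  construction, so the per-sample nugget `eta_i` absorbs
  `1/4 - gamma - sum_k w_ik^2 (alpha0_k + phi_k)` rather than measuring
  within-sample variance on an absolute scale. `eta` estimates should not be
  interpreted as inbreeding coefficients.
* *Confounding.* For K=1, `gamma` and `phi` enter every off-diagonal entry
  identically and only their sum is identified; `alpha0` and `phi` are
  partially confounded whenever sampled distances do not reach the kernel's
  plateau. Admixture proportions in a covariance mixture are identified up
  to near-affine remappings of the simplex whenever layer kernels are
  similar; the data pin them down through samples of (nearly) pure ancestry
  and through kernel-shape differences, and the sparse Dirichlet prior
  resolves the remainder toward the corners. Expect a few percent of
  admixture mass to remain "smeared" into unused layers in finite chains.

## Priors and parameterization

Half-Gaussian(scale 1) priors on `alpha0`, `alphaD`, `phi`, `gamma`, `eta`
(weakly informative once distances are normalized to mean 1 and given
`|omega_hat| <= 1/4`), uniform(0, 2) on the kernel shape `alpha2`, and an
independent symmetric Dirichlet with concentration `1/K` on each admixture
row — sparsity-inducing, harsh against intermediate admixture, so unused
layers are pushed toward zero weight. All scales and the concentration are
configurable (`PriorSettings`).

Sampling runs in an unconstrained space: logs of positive parameters, a
scaled logistic for `alpha2`, stick-breaking for each admixture row (with
offsets so the zero vector is the barycenter). Two non-obvious choices:

* **Diagonal block.** Instead of `log eta_i` the sampler carries
  `log d_i` with `d_i = gamma + sum_k w_ik^2 (alpha0_k + phi_k) + eta_i`,
  the total model diagonal, recovering `eta_i` by subtraction (rejecting
  draws where it would be nonpositive). The observed diagonal pins `d_i`
  within a fraction of a percent, so parameterizing it directly decouples
  kernel amplitudes from the nugget; with `log eta` every amplitude move
  needs a compensating nugget move and the chain crawls.
* **Rejection, not repair.** Non-positive-definite proposals get log density
  `-inf`; matrices are never jittered. Public evaluation functions raise a
  `NotPositiveDefiniteError` carrying the smallest eigenvalue.

## Posterior sampling

The sampler is an adaptive Metropolis-within-Gibbs kernel:

1. one Gaussian random-walk update per coordinate per sweep, step sizes
   tuned toward 0.44 acceptance in batches of 25 during warmup
   (diminishing-adaptation batch rule);
2. per-layer block proposals over the four kernel parameters, using the
   corresponding block of the empirical covariance of the chain history;
3. two full-vector proposals per sweep with covariance learned from the
   history (scaled `2.38/sqrt(dim)`, scale adapted toward 0.25 acceptance).
   These let the chain travel the soft ridge along which admixture scale
   trades off against kernel amplitudes, which coordinatewise moves cross
   very slowly.

All adaptation freezes at the end of warmup (default: half of `n_iter`;
package default 4 chains x 2000 sweeps). Chains initialize from a clustered
start: k-means on the rows of `omega_hat` gives hard layer assignments
(admixture rows at 0.92/0.08 corners), amplitudes come from within- versus
between-cluster mean covariances, and the non-admixture coordinates are then
profile-optimized by L-BFGS-B at fixed admixture. The admixture block is
deliberately *not* optimized: the unconstrained-space mode is biased toward
compressed admixture by the stick-breaking Jacobian, which is exactly the
artifact the clustered start avoids. Chains get overdispersed jitter
(sd 0.25 on kernel/global/diagonal coordinates, 0.05 on admixture) so
independent chains straddle the ridge. Because mixture posteriors are
invariant to permuting layer labels, chains are label-aligned (greedy
matching on mean admixture) before stacking; `match_layers` applies the same
alignment across independent runs.

Convergence reporting uses arviz split-chain R-hat and effective sample
size, with ESS capped at the draw count (the estimator can nominally exceed
it for near-independent draws). Kernel-shape parameters mix slowest — their
posterior is a genuinely wide ridge — and short chains will show large R-hat
there before the admixture summaries degrade.

## Model comparison

`cross_validate` partitions loci into random 90/10 train/test splits
(`partition_loci`, reproducible by seed, identical partitions for every
model: a paired design). Each model is fit to the training allelic
covariance with `df` = training locus count, and scored on the test
covariance (`df` = test locus count) by the log of the posterior-mean
likelihood, computed as log-mean-exp over per-draw Wishart log-likelihoods.
"Averaged over the posterior" admits a second reading — the posterior mean
of the log-likelihood — which is exposed as `method="mean-log"`; the
default is the predictive-density reading. The summary annotates as "best"
the simplest model (fewest layers, nonspatial before spatial) within one
standard error of the maximum, and leaves the decision to the user. When
judging whether accuracy keeps improving beyond some K, compare model means
with their standard-error bars (as read off the CV curve); paired
per-replicate differences have standard errors so small that practically
irrelevant gains of a fraction of a log-unit test as nonzero.

Layer contributions are defined as `A_k / sum(A)` with
`A_k = sum_{i<j} w_ik w_jk G_k(D_ij)`: the admixture-weighted within-layer
covariance mass over distinct pairs, excluding `gamma` (layer-independent)
and `eta` (diagonal). This is one reasonable reading of "relative
contribution to total covariance"; it is permutation-equivariant, zero for
unweighted layers, and computed at the posterior median when given draws.
The conventional 0.1% cutoff is only reported (a warning), never enforced.

## Synthetic data

Two generators with opposite purposes:

* `simulate_frequencies` is **model-exact**: per locus an N-vector is drawn
  from MVN(1/2, Omega(truth)) and clipped to [0, 1]; optional binomial
  resampling to the per-deme haploid sample size (default 20) adds finite-
  sampling noise. Admixture surfaces come from K Gaussian random fields on
  the deme lattice (squared-exponential correlation, default smoothness 1.5
  lattice units, softmax intensity 6) — spatially autocorrelated, corner-
  heavy with admixture concentrated in contact zones — plus a 3% uniform
  residual so no deme is exactly pure and interval coverage of the truth is
  well defined. Scenario presets k1/k2/k3 use a 6x6 lattice, 10,000 loci and
  deeply diverged layer kernels (`alpha0` 0.030-0.040, distinct `alphaD` and
  `alpha2`, `phi` 0.010-0.025, `gamma` 0.008, `eta` 0.003). Amplitudes were
  chosen once against an identifiability analysis: the Wishart noise floor
  per off-diagonal entry is ~0.25/sqrt(L) because of the fixed 1/4 diagonal,
  so admixture is sharply identified only when layer amplitudes are a few
  hundred times that floor. At these amplitudes clipping winsorizes ~1-3% of
  draws and deflates covariances by a few percent — a nearly multiplicative
  effect absorbed by the amplitude parameters, not by `w`. Calibration
  tests that compare empirical to parametric covariance entrywise use the
  same presets with amplitudes divided by 10, where the winsorization bias
  is far below Monte-Carlo noise.
* `simulate_lattice_ibd` is **deliberately misspecified**: a forward-time
  drift-migration diffusion on the lattice (eight nearest neighbors,
  diagonals included; default migration 0.05 toward the neighborhood mean,
  drift sd 0.05 per generation, 100 generations, ancestral frequencies
  uniform on [0.3, 0.7], whose variance surfaces as global covariance).
  It produces pure isolation by distance with no layers, but also
  non-stationary structure the kernel family cannot represent (boundary
  demes drift more; the eight-neighbor metric is not Euclidean). Spatial
  fits to it dominate nonspatial fits in cross-validation at every K, and a
  single layer carries ~95-98% of the covariance in an overfitted K=3
  model — but the last few percent is the extra layers absorbing *real*
  residual structure of this generator, not noise, so exact spurious-layer
  collapse is only observed on model-exact single-layer data. That is the
  behavior the tests encode.

What passing tests on these generators do **not** show: robustness to
coalescent linkage structure, to SNP ascertainment, to real missingness
patterns, or to sampling geographies far from a regular lattice.

## Problem sizes used by the test suite and acceptance script

Admixture recovery: 20 replicates of K=2 on a 5x5 lattice (N=25), L=10,000,
2 chains x 1200 sweeps (720 warmup). Cross-validation: one K=1 lattice-IBD
dataset (N=25, L=10,000), K in {1,2,3} x {spatial, nonspatial}, 3 paired
replicates, 2 chains x 900 sweeps. Spurious layers: K=3 spatial fit to one
k1-preset dataset on the 6x6 lattice with binomial resampling, 2 chains x
1000 sweeps. These are the package's scaled-down standard configurations;
larger chain counts and replicate numbers tighten all of the Monte-Carlo
margins.

## Known limitations

* Per-sample posterior uncertainty in admixture inherits the kernel ridge:
  with fewer than ~5,000 loci or weakly diverged layers, expect admixture
  credible intervals to widen substantially and layer labels to become
  unstable.
* The sampler is random-walk based; for N in the hundreds each sweep costs
  O(N) likelihood evaluations at O(N^3) each, and a gradient-based sampler
  would be preferable. Computation is independent of L after the covariance
  is formed.
* No binomial-likelihood variant (frequencies are always treated through
  the Wishart approximation), no per-locus frequency model, no
  marginal-likelihood model choice, no VCF/PLINK parsing (convert with e.g.
  `plink --freq` / `bcftools query` to the delimited table), no LD pruning
  or imputation.
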