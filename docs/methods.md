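# Methods

## The placement model

A reference panel of N individuals genotyped at L biallelic SNPs, with
population labels, anchors everything. Its standardized dosage matrix is
decomposed by SVD; the top-K score matrix Y (rows = reference individuals)
is the ancestry space S. K defaults to 4, which resolves continental-scale
structure; fine-scale (within-continent) panels typically also use the
top few PCs of a denser panel.

A study individual is never projected onto fixed loadings. Instead, for
each individual separately:

1. restrict the panel to the individual's non-missing sites shared with
   the panel (L′ of them);
2. run a PCA of the N+1 rows (panel + individual) on those sites,
   standardized jointly, keeping K′ ≥ K components (default K′ = 20);
3. fit the projection Procrustes map from the N reference rows' joint
   scores X onto their known coordinates Y, minimizing
   D = ‖ρ X_c A + 1bᵀ − Y‖² over orthonormal-column A (K′×K), ρ > 0, b;
4. push the individual's joint score through the fitted map.

The per-sample joint PCA is the price paid to avoid projection shrinkage:
a held-out sample projected onto loadings estimated from the panel alone
is systematically contracted toward the origin, whereas here the sample
helps define S′ and the Procrustes map only rotates/scales/translates,
never contracts individual axes.

Assumptions: sites are treated as exchangeable and unlinked; dosages are
additive allele counts; the panel spans the ancestry of the study samples
(violations are what the Z diagnostic detects, not what the placement
corrects).

## Solving the projection Procrustes problem

For K′ = K this is the extended orthogonal Procrustes problem with the
closed-form solution A = UVᵀ from the SVD of X_cᵀY_c and
ρ = trΣ/tr(X_cᵀX_c). For K′ > K no closed form exists, because
‖X_cA‖² = tr(AᵀX_cᵀX_cA) depends on A: profiling out ρ and b leaves
maximization of tr(AᵀC)²/tr(AᵀSA) (C = X_cᵀY_c, S = X_cᵀX_c) over the
Stiefel manifold. Zero-padding Y to K′ columns and solving the square
problem is *not* equivalent — it penalizes all source variance outside
the target subspace and shrinks ρ by exactly the fraction of variance the
K target dimensions cannot represent (measured on this package's default
study conditions: similarity drops from ≈1.0 to ≈0.73 at K′ = 20, K = 4).

The solver therefore uses the classical target-augmentation iteration:
append K′−K *free* columns W to Y_c, solve the square problem in closed
form, refresh W with the mapped extra coordinates, repeat. Each sweep is
monotone in the residual; at the fixed point the free columns absorb the
unfitted variance and D is the true minimum over the real K columns.
Numerical choices:

- convergence when a sweep improves D by less than 1e-14·tr(Y_cᵀY_c),
  capped at 5000 sweeps per start;
- the profiled objective is non-convex in A; on random unstructured
  instances roughly 1% of zero-padded starts converge to a spurious fixed
  point, so the solver restarts from 7 additional deterministic
  pseudo-random orthonormal completions (internal fixed seed; results are
  reproducible) and keeps the best D. Restarts stop early when
  D ≤ 1e-9·tr(Y_cᵀY_c), since no alternative optimum could improve a
  near-perfect fit by more than D itself;
- for K = 1 the profiled ratio is scale-invariant, so the exact optimum
  u ∝ S⁻¹c is added as a candidate (via least squares, robust to
  singular S);
- ρ and D are re-profiled from the winning A (ρ = tr(AᵀC)/tr(AᵀSA)),
  which is exact for fixed A and removes the last-sweep lag;
- ties or zeros among the singular values at the solution make A
  non-unique without affecting D; a warning is emitted. This routinely
  happens at K′ = N (trailing joint components are noise) and is
  harmless.

The similarity t = √(1 − D/tr(Y_cᵀY_c)) is not printed in most tool
documentation; this definition follows the method lineage, normalizing by
the *target* (reference) variance so t is comparable across study
individuals sharing one panel. t = 1 iff D = 0; tiny negative radicands
are clamped.

### Self-placement exactness and the choice of K′

With center-only standardization and a full-data study sample, the
reference rows' *full-rank* joint scores are an exact rotation of the
reference-only configuration, so at K′ = min(N, L′) a replayed reference
individual lands on its own coordinates to machine precision. Truncating
to K′ = 20 tilts the retained axes by O(1/N) (the study row's weight in
the joint covariance), which still yields t ≥ 0.999 but moves coordinates
by ~0.1–1% of ‖Y‖. Validation of the exact self-placement property
therefore runs at full joint rank; routine analyses keep K′ = 20, where
the placement differences are far below between-population distances.

## Standardization

Missing dosages are imputed with the column mean before centering.
`center_only` (the default) subtracts column means; `center_scale` also
divides by √(p̂(1−p̂)), p̂ = mean/2, with zero-variance columns assigned
scale 1. Center-only is the default because frequency scaling inflates
the weight of low-frequency sites, and because the self-placement
exactness above holds exactly only without sample-dependent rescaling.
Joint PCA recomputes statistics from all N+1 rows; the Procrustes step
absorbs the resulting frame difference.

## Sequence mode

The study sample contributes dosage 2 − 2·(ref reads)/(depth) at each
covered site — deliberately uncorrected for base error, because the
reference individuals are simulated *with* that error: at each site with
genotype g, coverage c (the study sample's own depth) and error rate ε,
alt reads ~ Binomial(c, (g/2)(1−ε) + (1−g/2)ε) and the simulated dosage
is 2·alt/c. Matching the noise on both sides is what makes the joint PCA
geometry, and hence the placement, comparable between a noisy study
sample and the clean panel. With `reps > 1` the stochastic placement is
repeated and coordinates/t averaged (t_sd reported); the default is a
single repetition, which the concordance results show is adequate at 5×.
Randomness is per-sample: each sample's stream is seeded by a SHA-256
hash of (master seed, sample_id), so batch order and worker count never
change any output byte.

## Diagnostics

- **k-nearest-neighbor composition** (default k = 20, capped at N):
  population fractions among the k nearest reference individuals in S;
  ties in distance break toward the lower reference index.
- **Z score**: the genetic-variance statistic
  v = mean_ℓ (g_ℓ − 2p_ℓ)²/(2p_ℓ(1−p_ℓ)), with p the panel alt-allele
  frequency clipped to [0.01, 0.99], has expectation 1 for an individual
  drawn from the panel's frequencies under Hardy–Weinberg. Z standardizes
  the study individual's v against its k neighbors' v on the same sites
  (k ≥ 5 required; sd = 0 yields Z = 0 with a warning); |Z| > 3 flags the
  sample. The exact variance definition used by the original server is
  not public; this reconstruction is isolated behind
  `genetic_variance_statistic` so an alternative is a one-function swap,
  and only the qualitative behavior (calibrated in-panel, strongly
  elevated for out-of-panel ancestry) is asserted by the tests.

## Synthetic data

The generator follows the Balding–Nichols model: ancestral frequencies
p ~ Uniform(0.05, 0.95) (avoiding near-monomorphic sites that destabilize
scaling), population frequencies q ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
divergence F, genotypes ~ Binomial(2, q). Defaults — 3 populations × 50
individuals, 2000 unlinked SNPs, F = 0.1, 5× Poisson coverage, 1% base
error — emulate a small continental-scale panel with shallow sequencing;
study individuals can be population draws, admixture mixes (genotypes
from Σ_a α_a q_a), or an absent outgroup at its own divergence (default
scenario F = 0.2) for exercising the Z diagnostic. What it does *not*
emulate: linkage disequilibrium, realistic demography and admixture LD,
batch/platform artifacts, genotyping error, or reference-panel
imputation. Tests passing on these fixtures show the estimator machinery
is correct under the model's assumptions, not that real panels of any
particular composition are adequate for any particular cohort.

Validation problem sizes (self-placement and recovery at N = 150,
L = 2000; concordance on 100 individuals; oracle comparisons on instances
with N ≤ 20) were chosen so the full suite runs in a few minutes while
keeping every statistical check well-powered.

## Degenerate inputs and edge policies

- Sites: matched by (chrom, pos); alleles reconciled exactly or by
  REF/ALT swap (dosage complemented); strand flips never attempted;
  multi-allelic and non-SNP records dropped.
- A study sample needs ≥ `min_loci` (default 100) usable shared sites;
  below 1000 a warning notes reduced stability, below the floor the
  sample fails (collected, not fatal, in batch runs).
- K′ is capped at min(N, L′) with a warning; if the cap falls below K the
  sample fails.
- Entirely missing study vectors, all-missing panel columns without
  supplied means, zero-variance Procrustes targets and rank-deficient
  sources raise typed errors.

## Known limitations

- The Z statistic is a reconstruction (see above); its absolute flag
  rates depend on the variance definition, though its separation behavior
  does not.
- Admixed individuals receive a single point estimate between their
  parental clusters, not admixture proportions.
- Samples are placed strictly one at a time; related study individuals
  are not modeled jointly.
- The per-sample joint PCA costs one SVD per individual; this is linear
  in cohort size and parallelizes trivially, but is not optimized for
  panels beyond ~10⁴ × 10⁶ in this implementation.
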