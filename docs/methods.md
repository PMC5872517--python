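# Methods

## The model

`rgsem` infers a directed molecular network from four matched data layers —
DNA copy number, DNA methylation, mRNA expression and protein expression —
for `p` genes measured on `n` samples. The central object is a two-layer
Gaussian simultaneous-equation model (SEM)

    Y = A Y + B X + E_Y        E_Y ~ N(0, Σ_Y),  Σ_Y = diag(σ_1 … σ_p)
    Z = C Z + D Y + E_Z        E_Z ~ N(0, Σ_Z),  Σ_Z = diag(λ_1 … λ_p)

where `X` (2p × n) interleaves copy number and methylation per gene, `Y`
(p × n) is gene expression and `Z` (p × n) protein expression. `A` and `C`
have zero diagonals and may contain cycles — including reciprocal pairs
a_ij, a_ji ≠ 0, i.e. feedback loops, which DAG-based methods cannot
represent. `B` is restricted to *cis* action: row `i` may load only on the
copy number and methylation of gene `i` (columns 2i−1 and 2i in 1-based
terms). Provided I−A and I−C are invertible, the model defines

    p(Y, Z | X) = p(Z | Y) · p(Y | X)
    Y | X ~ N((I−A)⁻¹ B X,  (I−A)⁻¹ Σ_Y (I−A)⁻ᵀ)
    Z | Y ~ N((I−C)⁻¹ D Y,  (I−C)⁻¹ Σ_Z (I−C)⁻ᵀ).

The layering encodes the central dogma: DNA features affect only their own
gene's transcription, transcripts drive proteins, and nothing feeds back
from protein to RNA or from RNA to DNA. These fixed directions are what
make the orientation of the remaining edges estimable.

### Graph semantics

The SEM corresponds to a *reciprocal graph* (RG): directed edges at the
nonzero entries of the coefficient matrices, undirected edges at nonzero
covariances between exogenous variables; cycles are allowed, and the only
structural rule is that no directed edge joins two nodes connected by
undirected edges. Conditional independence is read off the graph by
moralization: `Z_A ⊥ Z_B | Z_C` whenever C separates A and B in the moral
graph of the subgraph induced by the minimal anterior set of A∪B∪C (the
closure of the query set under repeatedly adding parents and undirected
neighbours). `rgsem.graph` implements this machinery directly — path
components, boundaries, anterior sets, moralization and separation by node
deletion — and `global_markov_query` answers arbitrary queries for
undirected, acyclic, chain and reciprocal input alike. The algebraic
counterpart, `rgsem.sem.gaussian_ci`, declares `Z_A ⊥ Z_B | Z_C` when every
entry of the Schur-complement partial covariance of the correlation-
standardized variables is below 1e−8; the test suite verifies on hundreds
of random SEMs that graph separation always implies a vanishing partial
covariance and that the converse holds in ≥ 99% of sampled queries
(faithfulness is generic but not guaranteed, so converse failures are
counted, not failed).

## Priors

Every structurally free coefficient carries a latent Gaussian value that
enters the model only when its magnitude clears a row-level threshold:

    a_ij = ã_ij · 1(|ã_ij| > tY_i)     ã_ij ~ N(0, τ_ij),  τ_ij ~ IG(α_τ, β_τ)
    tY_i ~ Uniform(0, t0)

with the analogous construction for the cis entries of `B` (sharing row
threshold tY_i) and for `C` and `D` (sharing a per-row protein-layer
threshold tZ_i). The threshold creates exact zeros — edge exclusion — and
has the interpretation of a minimum biologically meaningful effect size per
response. Error variances get conjugate inverse-gamma priors
σ_j, λ_j ~ IG(a, b).

Defaults: `t0 = 1`, `α_τ = β_τ = 1`, `a = b = 0.01`. The threshold cap of 1
is calibrated to data whose rows are on a roughly unit scale (the loader
standardizes by default; the synthetic benchmark works on the simulation's
native scale where effects are ~1). The protein-layer threshold structure
(one tZ_i per protein, shared across the C and D rows) mirrors the gene
layer; it is a design choice of this package. Prior-recovery and
calibration tests use moment-proper hyperparameters (e.g. IG(3, 2)) because
the weakly-informative defaults have no finite moments to test against.

## Posterior computation

The sampler is Metropolis-within-Gibbs over (latents, thresholds, scales,
variances), JIT-compiled (numba) on Gram-matrix sufficient statistics
(Y Yᵀ, Y Xᵀ, X Xᵀ, Z Zᵀ, Z Yᵀ), so a single-coefficient update costs
O(p²) plus one small log-determinant, independent of n. One sweep:

1. **Coefficients.** Each free latent is updated by Metropolis with an
   independence proposal: with probability ½ a uniform draw on the spike
   (−t_i, t_i), otherwise a draw from the Gaussian proportional to
   (row likelihood) × N(0, τ) — exact because the row residual sum of
   squares is quadratic in a single coefficient. For entries of `A` and `C`
   the n·log|det| term enters the acceptance ratio. This proposal jumps
   directly between exclusion and the conditional slab mode; a symmetric
   random walk (sd 0.1) and plain prior draws remain available
   (`proposal="rw"` / `"prior"`).
2. **Exchange moves.** Two involutive proposals cross between nearly
   likelihood-equivalent structures that single-site updates cannot
   connect: a direction swap exchanging (ã_ij, ã_ji), and, in the protein
   layer, a swap of c̃_ij against d̃_ij ("protein j regulates protein i"
   vs "gene j regulates protein i"). A joint conditional proposal for both
   members of a reciprocal pair handles feedback loops, whose posterior
   trades a large n·log|det(I−A)| penalty against small residuals and is
   unreachable by one-at-a-time births.
3. **Thresholds.** t_i is drawn *exactly* from its full conditional: given
   the latents the likelihood is piecewise constant in t_i, with
   breakpoints at the latent magnitudes, so segment masses (prior length ×
   likelihood of the implied active set) can be enumerated and sampled.
4. **Scales and variances.** Conjugate Gibbs draws
   τ | ã ~ IG(α_τ + ½, β_τ + ã²/2) and
   σ_i | · ~ IG(a + n/2, b + RSS_i/2) with RSS_i the squared-residual sum
   of row i of (I−A)Y − BX (λ analogous).

Any proposal that would make I−A or I−C numerically singular
(reciprocal condition number < 1e−10) is rejected.

**Initialization.** The default start is the *empty network*: thresholds
and scales from their priors, all latents zero and error variances set to
the marginal data row variances. A dense random start is dangerous in this
model: large random coefficients inflate the residuals, the variance Gibbs
step then inflates σ, the likelihood flattens, and an arbitrary dense web
consolidates before the variances can shrink. Prior-draw and per-row
ridge-regression starts remain available (`init_strategy`).

**Annealed burn-in.** The posterior over network structures is severely
multimodal (near-equivalent orientations, compensating webs). During
burn-in only, the likelihood is tempered through `anneal` melt/freeze
cycles (default 2): β ramps 0.05 → 1 over 80% of each cycle. At the end of
each cycle (and periodically at β = 1) the state is scored by its
untempered log joint density, and the best snapshot becomes the starting
point of the sampling phase. Because every retained draw comes from the
exact, untempered kernel, this only chooses the chain's starting point;
burn-in draws are discarded as usual. A single seeded RNG stream with a
fixed update order makes traces bit-reproducible.

## Edge calling

The posterior probability that an edge is present, e.g.
p(a_ij ≠ 0 | X, Y, Z), is estimated by the Monte-Carlo average
(1/L) Σ_l 1(a_ij^(l) ≠ 0) over the L retained draws; the thresholded prior
makes the indicator exact. Edges with PIP at or above a cutoff — default
0.5, the median-probability model; the cutoff is a mandatory, logged
parameter — are assembled into a typed network over 4p nodes
(`<gene>.c/.m/.g/.p`), each edge annotated with the sign of the posterior
mean of its included draws. Degrees count incident called edges (in + out),
each called directed edge once; a reciprocal pair therefore contributes two
to each endpoint.

## Synthetic benchmark

The generator draws ground truth from the model class itself: free entries
of A, C, D nonzero independently with probability `sparsity`, cis entries
of B with probability 0.9, magnitudes uniform on [effect_low, effect_high]
with random sign, resampled until I−A and I−C have reciprocal condition
number above 1e−6. Exogenous (copy number, methylation) pairs are bivariate
standard Gaussian with within-gene correlation 0.3 — a fixed, stated
assumption mimicking realistic coupling; the model conditions on X and
never models it. The fixed recovery scenario is p = 5 genes, n = 300
samples, sparsity 0.15, effects in [0.8, 1.2], error SD 0.5 (variances
0.25), fitted on the simulation's native scale with the default sampler at
20,000 iterations, 5,000 burn-in, thinning 10; replicate `s` uses data seed
`s` and chain seed `s + 100`, with canonical replicates 1–10. Scores are
ROC AUCs of the PIP ranking over all structurally free coefficients.

What the generator does *not* emulate: non-Gaussian noise, outliers,
missing values, batch effects, measurement error in X, discrete genotypes,
or sample heterogeneity. Passing recovery benchmarks therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness on real tumour data.

## Numerical choices and degenerate inputs

- Variance parameters σ, λ are *variances*, not standard deviations.
- I−A, I−C rejected as singular below reciprocal condition number 1e−10
  (1e−6 at generation time, to keep simulated data finite-variance).
- `n = 0` datasets are legal and yield prior sampling (used by the
  prior-recovery tests).
- Residual sums of squares are clamped at zero against cancellation error.
- Ties in the posterior-mean sign (exactly zero) are reported as `0`
  (ambiguous); degree tables break ties by label.
- Row standardization uses the unbiased (ddof = 1) sample SD; constant rows
  are left unscaled.

## Known limitations

- The protein layer (C, D, λ) is not globally identified: the conditional
  law of Z given Y determines only the mean map (I−C)⁻¹D and the residual
  covariance, leaving a likelihood-flat manifold of parameterizations.
  Sparsity (the thresholded prior) and the gene→protein anchors in D
  resolve it in practice, but when a protein has no RNA driver the
  orientation of its protein–protein edges can be genuinely ambiguous, and
  PIPs split across the orientations.
- Feedback pairs with loop gain a_ij·a_ji near 1 produce near-singular
  I−A; the data then carry enormous variance along one direction and both
  mixing and identification degrade. The joint pair moves and annealed
  burn-in recover most but not all such cases at the default chain length.
- Inference assumes homogeneous samples and linear Gaussian relationships;
  discrete data (SNPs, mutation status) are out of scope.
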