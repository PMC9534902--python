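# Methods

## Model

Each genome is treated as a community of protein-domain families. The
abundance x(t) of one family follows the stochastic growth equation

    dx/dt = r·x − x·g(x) + x·σ_r(x)·dB/dt,   σ_r²(x) = σ²ₑ + σ²_d/x,

with constant net growth rate r = b − d (duplication minus
inactivation), environmental variance σ²ₑ (proteome-wide disruptions
such as horizontal transfer acting on all copies at once), demographic
variance σ²_d (copy-level reproduction differences), and a density
regulation g(x) that prevents divergence — the genome is a finite
resource. New families arrive by an inhomogeneous Poisson innovation
process and evolve independently (neutral equivalence across families).

The stationary family-abundance intensity λ(x) has closed forms for the
two regulation modes implemented here (ε = σ²_d/σ²ₑ):

* **Gompertz**, g(x) = γ·ln(x+ε):
  λ(x) ∝ (x+ε)⁻¹ exp{−[ln(x+ε) − r/γ]² / (σ²ₑ/γ)}, which for ε ≪ x is a
  Log-Normal in x with μ = r/γ, σ² = σ²ₑ/2γ. Sampled with Poisson noise
  the observable RSA is a **Poisson Log-Normal** (PLN).
* **Linear**, g(x) = η·x: λ(x) is a Gamma with shape α = 2(r+ηε)/σ²ₑ and
  rate β = 2η/σ²ₑ; the observable RSA is a **Negative Binomial** (NB)
  with dispersion α and success rate q = σ²ₑ/(2η+σ²ₑ). As α → 0 the
  zero-truncated NB converges to the **Log-Series** (LS), q^x/(x·(−ln(1−q))).

Because absent families are unobservable, all fitting is on the
zero-truncated laws p(x)/(1 − p(0)), x ≥ 1 (the LS is already
zero-free). The maps between ecological rates and distribution
parameters imply the diagnostic linear relation μ = 2rσ²/σ²ₑ: genomes
sharing (r, σ²ₑ) but differing in regulation strength γ fall on a line
through the origin in the (σ², μ) plane with slope 2r/σ²ₑ.

Model choice is by AIC = 2k − 2·lnL (k = 2 for PLN and NB, 1 for LS),
ties broken by fewer parameters then the fixed order PLN < NB < LS so
pipelines are reproducible. Selection of the PLN over NB/LS is read as
evidence of Gompertzian (log-damped) growth: rare families proliferate
relatively faster than abundant ones.

## The RSA distance

Each genome with a converged PLN fit is summarised by (μ, σ, density):
σ is the standard deviation √σ² (configurable to σ² for sensitivity
analysis), and density is total domain copies N divided by genome
length in bp — N counts instances, not distinct families, since it
describes how densely the genome is populated. Each coordinate is
z-scored across genomes (n−1 denominator; with z-scoring the ddof
choice only rescales all distances by a common factor) and the distance
is Euclidean in the scaled space, hence a true metric. Genomes missing
a converged fit or a density are reported in an exclusion list and
dropped from every downstream comparison, never imputed.

## Clustering and comparison

RSA distance matrices are clustered with Ward linkage (the squared
Euclidean Lance–Williams update applied to the distance input — the
"Ward.D2" convention); 16S matrices, not being Euclidean, use average
linkage. Trees are cut to exactly k clusters by undoing the k−1 last
merges in merge order, which also resolves tied heights
deterministically.

Partition agreement is normalized mutual information with the
arithmetic-mean normalization (sqrt/min/max are accepted options); a
zero-entropy partition scores 0 by convention. NMI is biased upward
when clusters are many relative to points, so a simulated baseline
assigns each point an independent uniform label in 1..k and scores
against the reference; the full sample of baseline values is returned.
Purity is the size-weighted average over clusters of the majority-taxon
fraction. Taxonomic comparisons keep only genomes whose label at the
chosen rank is known and shared by at least 10 genomes (configurable).

Tree agreement uses (i) the Pearson correlation of cophenetic distance
vectors and (ii) the shared-node fraction 2·|common internal leaf sets|
/ (m₁ + m₂). The second measure counts internal nodes only — leaves are
trivially always shared — and is the plain shared-fraction variant; a
Baker-style correlation restricted to common nodes would be an
alternative reading of the same phrase, and the ambiguity is resolved
here in favour of the simpler, parameter-free statistic.

The robustness protocol draws, for each proportion p and repeat, a
uniform subsample of round(p·F) domain families among those present in
at least one selected genome, reruns RSA → PLN fit → features →
distances → tree, and records both correlations against the all-family
tree. A genome whose subsampled proteome becomes empty or unfittable is
dropped from both trees for that repeat (the base tree is re-clustered
from its cophenetic distances restricted to the surviving leaves) and
counted in the output table.

## 16S distances

Gene copies are aligned globally with affine gaps (Gotoh): match +1,
mismatch −1, gap open −2, gap extend −1, a gap run of length L costing
open + (L−1)·extend. Traceback ties prefer diagonal, then up, then
left, making the emitted alignment deterministic. 'N' scores as a
mismatch against everything, itself included; other ambiguity codes are
rejected rather than guessed. The distance between aligned sequences is
differing columns over counted columns, where a run of gap columns
counts as one difference under the default "onegap" rule ("eachgap" and
"nogaps" are options) and terminal gap runs are counted unless
count_ends is false. A genome pair's distance is the mean over all
cross pairs of copies; the resulting matrix need not satisfy the
triangle inequality and is used as-is for average-linkage clustering.

## Synthetic data

The generator works directly in (μ, σ², density) space — the space the
method operates in — rather than simulating the innovation process:
each group has a centre, per-genome Gaussian jitter, S families drawn
i.i.d. from the zero-truncated PLN, family identities drawn from a
shared pool with group-biased weights (70% of the probability mass on a
group-specific block by default), and genome length set so the realized
density matches the jittered target. Default study conditions for the
end-to-end checks: 4 groups × 50 genomes, S = 2000 families per genome
(the order of magnitude of real annotated bacterial proteomes), group
centres 1.2 apart in μ and 0.8 in σ², densities 0.8–3.2 × 10⁻³
domains/bp, jitter 0.05. At much smaller S the sampling error of μ̂
(≈ 0.36 at S = 2000 for μ = −3, σ² = 4) would swamp the group
separation — a real constraint of the method, not of the tests.

What the generator does **not** emulate: phylogenetic correlation
between groups, horizontal transfer, pseudogenization, genome
reduction, shared-family covariance structure beyond the biased pool,
or 16S secondary structure (16S-like sets are i.i.d. per-site mutations
of group ancestors derived from one random ancestor). Passing tests
therefore demonstrate statistical correctness of the machinery on data
satisfying the model's own assumptions, not performance on real
genomes.

The optional SDE simulator integrates the growth equation by
Euler–Maruyama with drift m(x) = [r − g(x)]x + σ²_d/2 + σ²ₑx/2 and
diffusion x·σ_r(x); with this drift ln x under Gompertz regulation is
an Ornstein–Uhlenbeck process whose stationary mean and variance are
exactly μ = r/γ and σ² = σ²ₑ/2γ, which the tests verify. Positivity is
kept by reflection at x_min = 10⁻⁶ (reflections are counted and
reported); extinction dynamics are out of scope.

## Numerical choices

* **PLN likelihood.** P(x) = ∫ Poisson(x; λ) LogNormal(λ; μ, σ²) dλ is
  integrated in u = ln λ by Simpson's rule on a per-x grid of 801
  points centred at the integrand's mode (Newton) and scaled by its
  local curvature width 1/√(e^u* + 1/σ²), spanning ±25 widths, all in
  log space. Fixed Gauss–Hermite rules centred on the mixing density
  were tried first and rejected: their error plateaus around 10⁻⁵–10⁻⁶
  in the small-μ/large-σ² regime typical of domain RSAs, enough to bias
  the MLE visibly along the flat likelihood ridge. The mode-centred
  Simpson rule is accurate to ~10⁻¹³ against a dense-grid oracle and
  remains exact in the σ² → 0 Poisson limit. Evaluations are chunked at
  4096 abundance values to bound memory.
* **Optimization.** σ² and α are optimized on the log scale, q on the
  logit scale, with method-of-moments starts. The zero-truncated
  likelihood forms a curved, nearly flat ridge in (μ, σ²); a
  Nelder–Mead pass alone stalls on it, so the fit polishes with
  L-BFGS-B (numerical gradients) from both the simplex solution and the
  moment start and keeps the best. Convergence is declared when the
  optimum is finite and away from the transform boundaries; boundary
  solutions (e.g. LS q → 0 when every abundance is 1) are returned with
  converged = false rather than raised.
* **Standard errors** come from the observed information: a central
  finite-difference Hessian of the negative log-likelihood in the
  natural parameter space at the optimum; non-invertible cases yield
  None rather than a number.
* **Preston R².** Abundances are binned into half-open doubling octaves
  [2^k, 2^{k+1}) without boundary splitting. Expected octave counts are
  S·Σ_{x∈octave} p_zt(x) summed exactly over the observed octaves, with
  the analytic residual tail mass folded into the last octave so
  expectations total S. R² = 1 − SS_res/SS_tot against the octave-mean
  baseline; a single-octave RSA returns NaN (undefined). The R² target
  (octave counts vs per-x frequencies) is a genuinely open convention;
  octave counts are the default because fit quality is conventionally
  judged on the Preston plot.
* **Truncated sums** for normalization checks are capped at
  max(4 × observed max, the 1 − 10⁻⁹ quantile of the untruncated
  model), the LS quantile via an analytic geometric tail bound.
* **Degenerate inputs.** Genomes with S below a configurable minimum
  (default 10 distinct families) raise an "unfittable" error and are
  excluded and reported, mirroring upstream practice of dropping
  extreme RSAs rather than imputing them.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| min_species | 10 | smallest S accepted for fitting |
| nodes | 801 | PLN quadrature points per abundance value |
| linkage | ward (RSA) / average (16S) | clustering update rule |
| NMI normalization | arithmetic | mean of entropies in the denominator |
| baseline n_sims | 1000 | random-assignment simulations per (n, k) |
| proportions | 0.1–0.9 | domain subsampling fractions |
| match/mismatch/gap open/gap extend | +1/−1/−2/−1 | alignment scores |
| distance_rule / count_ends | onegap / true | gap handling in 16S distances |
| x_min (SDE) | 10⁻⁶ | reflection floor keeping abundances positive |

## Known limitations

* The (μ, σ²) likelihood ridge makes individual parameter estimates
  noisy at small S; group-level conclusions need either many genomes or
  S in the thousands.
* AIC occasionally (≈ 8% of replicates) prefers a small-dispersion NB
  over the LS that generated the data — the expected boundary behaviour
  of a nested one-parameter extension, visible whenever the two fits
  overlap.
* The 16S aligner is quadratic-time pure NumPy; it is meant for gene
  copies (~1.5 kb) at test scale, not for aligning whole databases.
* Robustness correlations compare trees rebuilt after dropping genomes
  lost to subsampling; with very low proportions and small proteomes
  many genomes can drop, making the reported correlations optimistic
  about the survivors only.
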