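# rsaphylo

Reference-free phylogenetic characterization of bacteria from the
ecology of their protein domains.

## The idea

A bacterial genome can be read as an ecosystem whose "species" are
protein-domain families and whose "individuals" are the copies of each
domain. Counting, for every family, how many copies a genome carries
yields the genome's Relative Species Abundance (RSA) distribution — the
histogram n_x of families observed with abundance x ≥ 1. Under a
birth–death–innovation diffusion with environmental variance σ²ₑ and
demographic variance σ²_d (Engen–Lande framework), the stationary RSA
depends on how growth is damped:

* Gompertzian regulation g(x) = γ·ln(x+ε) → **Poisson Log-Normal** (PLN)
  with μ = r/γ and σ² = σ²ₑ/2γ;
* linear regulation g(x) = η·x → **Negative Binomial** (NB) with
  dispersion α = 2(r+ηε)/σ²ₑ and success rate q = σ²ₑ/(2η+σ²ₑ);
* the α → 0 limit of the NB → **Log-Series** (LS).

`rsaphylo` fits all three distributions zero-truncated (absent families
are unobservable) by maximum likelihood, selects the best by AIC, and
summarises each genome by the triple **(μ, σ, domain density)**, where
density is total domain copies per bp. Genomes become points in this
3D space; after per-dimension z-scoring, the Euclidean distance between
points is the *RSA distance*. Hierarchical clustering of that matrix
gives a reference-free phylogeny that can be compared against taxonomy
and 16S rRNA gene distances via NMI (with a simulated random baseline),
purity, cophenetic correlation and shared-node fraction, and stressed
by the domain-subsampling robustness protocol.

## Worked example

```python
from rsaphylo import GroupSpec, PLNParams, RSAPhylogeny, nmi, purity
from rsaphylo.synthetic import generate_population

# a synthetic community: 3 groups of genomes with distinct ecology
specs = [
    GroupSpec(label=f"G{g}", pln=PLNParams(mu=-4.5 + 1.6 * g, sigma2=4.6 - 0.9 * g),
              density=0.0008 * (g + 1), genome_length=3_000_000,
              n_genomes=8, n_families=1200, jitter=0.05)
    for g in range(3)
]
matrix, records, labels = generate_population(specs, family_pool=5000, seed=2024)

results = RSAPhylogeny(matrix, records).fit(candidate_models=("PLN",))
print(results.summary())
clusters = results.clusters(k=3)
truth = {g: labels[g] for g in clusters}
print(f"NMI vs truth: {nmi(clusters, truth):.3f}  purity: {purity(clusters, truth):.3f}")
```

Output:

```
RSA phylogeny fit
  genomes fitted:     24 (excluded: 0)
  selected by AIC:    PLN 100.0%, NB 0.0%, LS 0.0%
  PLN Preston R^2:    mean 0.999, min 0.997
  mu range:           [-5.975, -0.866]
  sigma2 range:       [2.343, 6.533]
  distance matrix:    24 genomes
NMI vs truth: 0.883  purity: 0.958
```

The fit table reports, per genome, the fitted PLN (μ, σ²), the
log-likelihood and AIC of all three candidates, the selected model and
the Preston-octave R². Here the PLN wins in every genome — the
signature of Gompertzian (log-damped) growth — and the Ward cut of the
RSA distance tree recovers the three planted groups almost exactly
(one genome of 24 lands in a neighbouring group's cluster).

The same steps are available from the shell:

```bash
rsa-phylo simulate --groups 3 --genomes-per-group 8 --seed 2024 --out sim/
rsa-phylo fit      --matrix sim/matrix.tsv --meta sim/metadata.tsv --out fits.tsv
rsa-phylo distance --matrix sim/matrix.tsv --meta sim/metadata.tsv --out rsa.dist
rsa-phylo dist16s  --fasta sim/16s.fasta --out s16.dist
rsa-phylo compare  --rsa rsa.dist --ref16s s16.dist --meta sim/metadata.tsv --out cmp/
rsa-phylo robustness --matrix sim/matrix.tsv --meta sim/metadata.tsv \
    --proportions 0.1:0.9:0.2 --reps 5 --seed 42 --out robust.tsv
```

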