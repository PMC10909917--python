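# microeuk

Community-assembly analysis for microeukaryotic plankton ASV tables.

Freshwater microeukaryotes (green algae, fungi, ciliates, cryptophytes,
chrysophytes, …) sit at the heart of the microbial loop, acting both as
primary producers and as bacterivores. A recurring question in their
ecology is how much of community structure is governed by deterministic
environmental filtering versus stochastic drift and dispersal, and how
trophic function (phototrophy / mixotrophy / heterotrophy) shifts along
productivity gradients. `microeuk` implements the full statistical
pipeline used to answer these questions from an 18S rRNA amplicon survey —
a samples × ASVs count table, a PR²-style taxonomy, and sample metadata
with geographic coordinates and physicochemical variables — for
microbial ecologists who want each stage as a tested, reusable library
function rather than a one-off script.

## What it computes

**Sloan neutral community model (NCM).** Under neutral drift with
immigration, the local relative abundance *x* of a taxon with
metacommunity mean relative abundance *p* follows
Beta(*Nm·p*, *Nm*(1−*p*)), where *N* is the local community size (reads
per rarefied sample) and *m* the immigration probability. Its occurrence
frequency across communities is then

    F(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p)),   d = 1/N

and *Nm* is estimated by nonlinear least squares of observed frequencies
on F(p). Taxa outside a Wilson binomial envelope around the fitted curve
are partitioned as over-represented (*above*) or under-represented
(*below*); R² measures how much frequency variation neutrality explains.

**Distance-decay of similarity.** Pairwise Sørensen similarity χ_d is
regressed on geographic distance on the log-log scale,
log₁₀(χ_d) = (−2z)·log₁₀(d) + b, giving the community turnover rate *z*.

**Spatial eigenfunctions and variation partitioning.** PCNM axes
(eigenvectors of a truncated inter-site distance matrix) serve as spatial
predictors; environmental variables are square-root transformed (except
pH), VIF-pruned (threshold 10) and forward-selected; partial RDA on
Hellinger-transformed counts decomposes adjusted R² into pure
environmental, pure spatial, shared and residual fractions with
reduced-model permutation tests.

**Diversity and group tests.** Rarefaction (without replacement), TMM
normalization, richness/Shannon, Bray-Curtis, one-way PERMANOVA with
automatic exhaustive enumeration on small designs, NMDS, quadratic
(hump/U) productivity-response fits, t/ANOVA-LSD comparisons.

**Trait profiling and drivers.** Rank-addressed rules map lineages to
trophic modes; per-sample mode shares are related to environmental
gradients and to permutation-tested random-forest importance (%IncMSE
with a response-permutation null).

**Synthetic data.** Every estimator has a generator dual
(`microeuk.synthetic`): beta-binomial neutral sampling from a lognormal
metacommunity, log-linear similarity decay on a 40 km transect, and
trait-labeled communities whose mode shares follow specified hump/linear
environmental responses — each carrying its ground truth for recovery
tests.

## Worked example

Fit the neutral model to communities simulated at the model's own
assumptions (36 samples of 18,300 reads, 2,000-taxon lognormal
metacommunity, truth *Nm* = 337, i.e. *m* = 1.84%):

```python
from microeuk.synthetic import gen_metacommunity, gen_neutral_communities
from microeuk.ncm import ncm_analysis

p = gen_metacommunity(2000, seed=7)
table = gen_neutral_communities(p, nm=337.0, n_reads=18_300, n_samples=36, seed=8)
res = ncm_analysis(table, n_reads=18_300)
print(f"Nm = {res['Nm']:.1f}   m = {100*res['m']:.2f}%   R2 = {res['r2']:.3f}")
```

prints

```
Nm = 362.9   m = 1.98%   R2 = 0.913
```

— the fitted immigration rate recovers the generating 1.84% up to the
small positive bias of the detection-limit approximation (see
`docs/methods.md`), the high R² reflecting that these communities really
are neutral; the envelope partition puts 83.2% of ASVs in the neutral
fraction (10.0% above, 6.8% below).

The same analyses run from the shell:

```bash
microeuk simulate neutral --seed 3 --out data/
microeuk ncm --counts data/counts.tsv --depth 18300
microeuk run config.yaml        # full pipeline from a YAML config
```

`microeuk run` writes per-stage TSVs plus a `summary.json` with eight
blocks (preprocess, alpha, beta, decay, vpa, ncm, traits, rf), and is
bit-reproducible for a fixed seed.

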