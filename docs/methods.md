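# Methods

This note documents the models and procedures implemented in `microeuk`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical choices that affect results.

## Data model

The pipeline's currency is a samples × ASVs table of non-negative
integer read counts; taxonomy is an 8-rank PR²-style lineage per ASV
(domain … species, shorter lineages right-padded empty so rules can be
rank-addressed deterministically); metadata carries site, season, depth,
coordinates and twelve physicochemical variables (temperature, pH, DO,
Chl-a, NO3-N, NO2-N, NH4-N, TN, TP, PO4-P, CODMn, TOC). All tables are
TSV; the sample label is the join key, and the pipeline fails fast on a
sample present in counts but absent from metadata. BIOM import is out of
scope.

## Preprocessing

*Filtering.* ASVs are dropped when (i) unassigned (no or empty lineage),
(ii) any lineage rank matches an exclusion term (default: Metazoa,
Ulvophyceae, Streptophyta, Rhodophyta — non-target metazoans and
macrophyte/macroalgal lineages in an 18S plankton survey), or (iii) they
are global singletons (total count 1 across all samples; the standard
ASV-pipeline meaning of "singleton"). Filtering precedes rarefaction.

*Rarefaction.* Each sample is subsampled without replacement
(multivariate hypergeometric) to a common depth, default 18,300 reads —
the lowest sequencing depth in the survey design this package targets.
Alpha summaries (richness, Shannon) are means over `n_iterations`
(default 100) independent draws, which is why reported richness can be
non-integer; the count table passed downstream is the first iteration.
Samples below the depth are dropped with a warning.

*TMM normalization.* For beta diversity on normalized counts we compute
trimmed-mean-of-M-values factors: the reference sample is the one whose
upper-quartile count fraction is closest to the mean of those fractions;
per sample, M (log2 ratio of fractions vs the reference) and A (mean
log2 fraction) are computed over ASVs nonzero in both, the most extreme
30% of M and 5% of A are discarded (two-sided), and the surviving M are
averaged with inverse asymptotic-variance weights
1/((N−y)/(Ny) + (N_r−y_r)/(N_r y_r)). Factors are rescaled to geometric
mean 1. These trims are the conventional defaults of the normalization
scheme.

*Transforms.* Hellinger (square root of relative abundance) precedes
RDA; environmental variables are square-root transformed except pH,
which is already on a log scale.

## Diversity and group structure

Shannon's base is configurable (natural log by default; base 2 is
supported because published values in this literature sometimes imply
bits). PERMANOVA is the one-way distance-based partition: sums of
squares from squared inter-point distances, pseudo-F =
(SS_between/(a−1))/(SS_within/(n−a)). When the number of distinct label
permutations does not exceed the requested permutation count the null is
enumerated exhaustively and p is the fraction of distinct permutations
(observed included) with F ≥ observed; otherwise a seeded Monte-Carlo
with the +1 correction is used, so p is never 0. NMDS delegates to
non-metric MDS (isotonic regression, Kruskal stress-1, best of
`n_restarts` random starts). Productivity responses are quadratic OLS
fits classified hump/U/monotone by the sign of the curvature coefficient
and its t-test at α = 0.05; Chl-a productivity levels use half-open bins
0–2 / 2–5 / 5–11 µg/L with the last bin closed.

## Spatial analysis

Geographic distances are haversine on a 6,371,000 m sphere; the planar
projection for PCNM is the local tangent plane about the centroid (valid
for the ≲50 km extents this targets; cross-checked against haversine to
within 0.5%). Distance-decay regresses log₁₀(Sørensen similarity) on
log₁₀(distance); z = −slope/2. Pairs at distance ≤ 1 m (same site,
different depth) or with zero similarity are excluded — log₁₀ is
undefined there, and the depth effect is tested separately — with the
exclusion count reported. PCNM truncates the distance matrix at the
longest minimum-spanning-tree edge (keeping the site graph connected),
replaces larger distances by 4× the threshold, Gower-centers −½D², and
keeps positive-eigenvalue axes (> 1e-10), orthonormal, ordered by
eigenvalue, with each axis' largest-magnitude element made positive so
results are stable across linear-algebra backends.

## Ordination and variation partitioning

RDA is the canonical analysis of the fitted values of the multivariate
regression of the column-centered (Hellinger) community matrix on the
predictors; R² is the explained trace fraction and adjusted R² the
Ezekiel correction 1 − (1−R²)(n−1)/(n−p−1), with **p taken as the rank
of the centered design** so redundant columns do not inflate the penalty
(this is what makes the two identical predictor sets partition into pure
fractions of exactly zero). VIF pruning iteratively drops the
highest-VIF predictor until all VIF ≤ 10, ties dropping the later
column. Forward selection adds the predictor with the largest adjusted-R²
gain, tests it by reduced-model permutation (residuals of the
current model permuted, fitted values added back), and stops when the
candidate's p exceeds α = 0.05 — or, after adding, when cumulative
adjusted R² reaches the all-predictor model's adjusted R² (the classical
double stopping rule; the cap is checked after adding, since a strong
single predictor can legitimately exceed the noise-penalized global
adjusted R²). Two-set partitioning takes a+b, b+c and a+b+c from the
three RDAs and derives pure/shared/residual fractions by subtraction;
small negative adjusted fractions are reported unclipped as diagnostics.
All candidate PCNM axes with positive eigenvalues enter selection.

## Neutral community model

The fit minimizes Σ(f_i − F(p_i))² over Nm on a log₁₀ grid (200 points
over 10⁻²…10⁷) followed by bounded scalar refinement; the objective is
flat at large Nm, which is why the search is on the log scale with a
coarse-grid start. The detection limit is d = 1/N (one read), standard
for rarefied counts. Least squares is on untransformed frequencies so R²
is the fraction of frequency variance explained. The confidence envelope
is the Wilson score interval for a binomial proportion with success
probability F(p_i) and n = number of communities; ASVs above/below the
envelope form the non-neutral partitions, summarized as shares of ASV
richness and of reads. A solution at a search boundary is flagged
non-convergent.

**Known bias.** The generator draws reads ~ Binomial(N, x) with
x ~ Beta(Nm·p, Nm(1−p)) — exactly the model's sampling dual — but the
fitted curve uses the continuous detection-limit approximation
P(detect) ≈ 1 − BetaCDF(1/N), not the exact beta-binomial detection
probability 1 − B(a, b+N)/B(a, b). Fitting the exact expected curve
shows this approximation alone inflates fitted Nm by roughly +9% to +22%
as Nm grows from 10 to 1,000. A second, opposite effect appears at small
Nm: the per-taxon mean relative abundance over a few dozen samples is a
very noisy estimate of p under strong drift, and this errors-in-variables
noise attenuates the fit (≈ −29% at Nm = 10 with 36 samples). The two
effects roughly cancel in the ecologically typical regime — recovery is
within ±10% for Nm ≈ 100–340, the regime of freshwater plankton surveys
— and the envelope partition under a fully neutral truth settles near
82% neutral richness rather than 100%, because the same approximation
pushes a tail of common taxa outside the band. Tests assert recovery in
the regime where it holds and order preservation outside it.

## Trait profiling

Rules are (rank, name, mode, priority) rows; the rule matching at the
deepest lineage rank wins and ties break by priority, so classification
is independent of rule-file row order. The shipped default table covers
common freshwater lineages (Chlorophyta → phototroph; Cryptophyta,
Chrysophyceae, Dinoflagellata → mixotroph with genus-level heterotroph
overrides such as *Noctiluca*; Ciliophora, Cercozoa, fungal lineages →
heterotroph) and is an explicitly replaceable default — dinoflagellate
trophy in particular varies by genus, so any serious application should
supply its own rule TSV. Mode read proportions are over classified reads
with the unclassified fraction reported separately; mode richness plus
unclassified richness equals sample richness exactly.

## Random-forest importance

A bagged regression forest (scikit-learn decision trees, mtry = p/3,
default 1,000 trees in the function API) predicts a mode share from the
environment matrix. %IncMSE permutes one predictor per tree over that
tree's out-of-bag rows and measures the relative OOB-MSE increase.
Significance comes from a response-permutation null: the forest is refit
`n_null` times on shuffled y and each observed %IncMSE is compared
against its own null distribution, p = (1 + #{null ≥ obs})/(1 + n_null).
Model-level summaries are OOB explained variance and k-fold
cross-validated R². The pipeline default scales to 200 trees / 99 nulls,
which keeps the null calibration while making a full run take seconds;
the learner is the commodity part, the permutation inference the point.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the estimators
assume: lognormal metacommunity abundances (default σ = 2, a realistic
dominance structure for microbial surveys), beta-binomial neutral
sampling at the rarefied depth, exactly log-linear similarity decay with
Gaussian noise on the log scale along a 40 km transect, a two-season
sites × 3-depths design (8 spring + 12 autumn sites at 60 samples), and
trophic-mode shares with quadratic-in-Chl-a (peak 4 µg/L) and
linear-in-DO responses whose mean shares (~43% phototroph, ~10–12%
mixotroph, remainder heterotroph) mirror typical lake communities. They
do **not** emulate PCR/sequencing artifacts, taxonomic misannotation,
phylogenetic correlation among ASVs, spatially autocorrelated
environmental fields, or interactions between neutrality and the
environment — so passing recovery tests demonstrates estimator
correctness under the stated model, not robustness to real-data
violations of it.

Every generator records its ground truth (`SyntheticTruth`) beside the
data and is deterministic under a fixed seed.

## Problem sizes and reproducibility

Recovery tests run at the study's shape (36 or 24 communities of 18,300
reads from 2,000 taxa; 12-site transects with 100 replicates), which
keeps the full suite under two minutes; the pipeline smoke fixtures are
smaller (24 samples, a few hundred taxa) since they exercise plumbing,
not statistical power. The pipeline derives per-stage seeds from the
global seed as (seed × 1009 + stage index) mod 2³¹, so any stage can be
re-run standalone with its recorded seed; `summary.json` is
byte-stable across identical runs up to the config block.

## Limitations

- The NCM fit inherits the detection-limit approximation bias described
  above; treat |fitted Nm| differences below ~15% as within method error.
- PERMANOVA is one-way only (season, depth, productivity level), no
  interactions or strata.
- NMDS is a contract-level embedding (coordinates + stress); no
  Procrustes rotation or axis interpretation is provided.
- The trait table is a simplification to three modes; mixotrophy in
  particular is a continuum this representation cannot express.
- VPA fractions can be slightly negative; they are reported as-is and
  should be read as zero-ish, not clipped.
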