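# Methods

This note records the models behind each stage, the defaults and why,
the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Phenotype model and heritability

Replicated multi-environment phenotypes follow the balanced two-way
model y_ijk = μ + g_i + e_j + (ge)_ij + ε_ijk for accession i,
environment (year) j and replicate k. Variance components come from the
expected mean squares of the random-effects ANOVA:
σ̂²_e = MS_err, σ̂²_ge = (MS_GE − MS_err)/r, σ̂²_g = (MS_G − MS_GE)/(n·r).
Negative method-of-moments estimates are clamped to zero and logged —
standard EMS practice. F tests use the random-model denominators
(G and E against G×E, G×E against error). Unbalanced tables are
rejected outright rather than approximated: the target design (3
replicates × 2 years) is balanced, and a silent REML fallback would
change the estimator's meaning. Broad-sense heritability is reported on
the entry-mean basis, h² = σ²_g/(σ²_g + σ²_ge/n + σ²_e/(n·r)) × 100%.

CV% uses the sample (n−1) standard deviation — this convention, not the
population SD, reproduces the reference panel's printed CV values
(e.g. 100·2.16/4.42 = 48.87). Skewness is adjusted Fisher–Pearson and
kurtosis is excess (normal = 0), matching the near-zero values expected
for normal-looking traits. Box–Cox λ is chosen by grid search over
[−5, 5] in steps of 0.01 on the standard profile log-likelihood; a grid
rather than a line search makes λ̂ exactly reproducible, and 0.01
matches the precision at which λ is conventionally reported. Inputs
must be strictly positive; there is no automatic shifting. Outlier
removal is deliberately left to the user — no defensible automatic rule
exists for these traits.

## Marker QC, kinship, structure

QC retains markers with missingness < 20% and MAF ≥ 0.05, computed on
observed calls only; the filter is idempotent. Kinship is the VanRaden
centered genomic relationship matrix Z Zᵀ / (2 Σ p_j(1−p_j)), Z =
dosage − 2p, with per-marker mean imputation of missing calls. An
optional flag zeroes off-diagonal entries below 0.05, mirroring the
weak-relationship truncation some kinship programs apply; it is off by
default because truncation discards information and the truncated
matrix can lose positive semidefiniteness.

Structure covariates are the top-k principal components of the
standardized dosage matrix restricted to ≤ 5,000 markers at MAF ≥ 0.2
(seeded subsample). PCA replaces Bayesian admixture clustering: for a
fixed-effect correction only the column space of the membership matrix
matters, and PCs span it for well-separated groups. k defaults to 2,
the number of subpopulations the reference panel exhibits. PC signs are
fixed (largest-magnitude score positive) for determinism.

## Q + K mixed-model scan

The null model y = Xb + u + e, u ~ N(0, σ²_g K), e ~ N(0, σ²_e I), is
fitted by spectral REML over the single ratio δ = σ²_e/σ²_g: rotating
by an orthonormal complement of X and the eigenvectors of the rotated K
turns the restricted likelihood into a cheap 1-D function of δ,
optimized by bounded Brent search seeded from a 61-point log grid on
[10⁻⁵, 10⁵]. Markers are then tested by GLS with δ held fixed — the
P3D/EMMAX approximation, which at panel scale differs negligibly from
per-marker REML (an `exact` mode re-estimates δ per marker for small
n). Tests are two-sided t with df = n − rank([1|Q|g]). With K = I the
whole construction collapses exactly to OLS simple regression, which
the tests pin down to 1e-8.

Dosages are mean-imputed for the scan and flipped where needed so betas
are per minor-allele copy. Markers monomorphic after imputation get
p = 1 and a flag instead of being dropped, so the total test count m in
the FDR step always equals the marker count.

Per-SNP phenotypic contribution (%) is the squared partial correlation
between whitened dosage and whitened phenotype given the fixed effects,
×100 — equivalently the model-R² increment in the decorrelated space.
In the K = I limit this is the classical OLS partial R²; in the mixed
model it is one of several defensible "marker R²" definitions, chosen
here because it is bounded in [0, 100] by construction and reduces to
the textbook quantity.

FDR control is the rank/step-up rule: sort p ascending, select the
largest rank n with m·p₍ₙ₎/n ≤ q (q = 0.01 default). This is exactly
Benjamini–Hochberg in step-up form; the test suite verifies set-level
identity against an independent implementation on 1000 random vectors.
The reported p threshold is the largest selected p-value, and the
achieved FDR (m·P/n)×100% is carried in the result.

Allele-effect summaries report mean phenotype per dosage class and the
percent difference between homozygote classes,
100·(mean_high − mean_low)/mean_high.

## R-QTL determination intervals

The LD walk starts at a significant SNP and computes composite r²
(squared Pearson correlation of dosages, pairwise-complete) against
each successive flanking marker. The first marker with r² < 0.1 is
*included* as the border — its position bounds the interval; if the
chromosome end is reached with all r² ≥ 0.1, the terminal marker is the
border. Markers whose r² with the lead is undefined (monomorphic on the
complete pairs) stop the walk the same way: they carry no evidence of
linkage. Borders are always positions of mapped markers, never
interpolated.

When several significant SNPs occupy one region, each gets its own
walk, with two refinements. First, a significant SNP on the immediately
adjacent map position bounds the walk on that side (the two SNPs'
intervals then share the stretch between them); significant SNPs
further away do not stop the walk — they simply lead their own
intervals. Second, intervals whose borders coincide exactly are merged,
pooling their lead SNPs, so several peak SNPs inside one LD block
report a single determination interval. The merge is an extension for
tidier reporting and is logged whenever applied. Interval lengths are
(right − left)/1000 kb, rounded half-up to two decimals for display
(74.078 → 74.08) with full precision retained internally.

## Four-gamete haplotype blocks

Markers failing MAF ≥ 0.05, genotype rate ≥ 75% or the Hardy–Weinberg
exact test at p ≥ 0.001 (two-sided conditional enumeration, mid-p off)
are excluded. For each adjacent retained pair, the four two-locus
gamete frequencies are estimated by EM from unphased genotypes — only
double heterozygotes are phase-ambiguous, and EM splits them between
coupling and repulsion in proportion to the current estimates. A block
extends while at most three gametes exceed frequency 0.01; a visible
fourth gamete implies detected recombination and opens a new block. The
retained markers are thus partitioned into map-contiguous blocks. A
Mendel-error parameter from family-based software has no meaning for a
panel of unrelated inbred lines and is omitted. The generator exports
its phased haplotypes, so tests can check EM frequencies against direct
gamete counts (observed agreement better than 0.02 at n = 500).

## Candidate genes

Genes overlapping ±250 kb of a lead SNP are reported with distance 0 if
the SNP lies inside the gene, otherwise the distance to the nearer gene
edge, sorted by distance. Coordinates are 1-based inclusive throughout
(VCF/GFF3 convention).

## RR-BLUP genomic selection

RR-BLUP fits y = 1μ + Mu + e with u ~ N(0, σ²_u I). Markers are
centered by their training means; λ = σ²_e/σ²_u comes from REML on the
equivalent GBLUP kernel M Mᵀ (scaled by its mean diagonal so the ratio
stays well-conditioned), and effects are recovered through the dual
identity (MᵀM + λI)⁻¹Mᵀv = Mᵀ(MMᵀ + λI)⁻¹v, so cost scales with sample
count. With a user-fixed λ the fit is the literal closed-form ridge
solution with μ = ȳ (the REML path instead uses a GLS intercept).
Predictions impute missing dosages with training means; predictive
ability is the Pearson correlation of predicted and observed phenotypes
in the validation set.

The experiment runner crosses training fractions {0.4 … 0.8} with three
marker panels: all markers; markers significant in a Q+K GWAS
(kinship, PCs, scan and FDR selection all recomputed inside the
training fold, so validation phenotypes can never leak into marker
selection); and per-replicate random panels of matched size. An empty
within-fold significant set falls back to the top-20 markers by
p-value, always logged. Replicate phenotypes are averaged per accession
before GS. Defaults: 100 repetitions, q = 0.01 within-fold, fraction
0.6 recommended for downstream use as the best ability/SD compromise.

## Synthetic-data generator

The generator emulates the reference panel's structure: ~520 inbred
accessions in two subpopulations, ~31.8k SNPs across the 19 B. napus
pseudochromosomes (A genome ~25 Mb, C genome ~40 Mb per chromosome,
markers proportional to length), MAF drawn uniformly on [0.05, 0.5],
2% missingness, and weak divergence (default Fst 0.05) via
Balding–Nichols Beta frequencies around a shared ancestral frequency.

LD comes from first-order Markov copying *of the latent uniform* along
each haplotype: at each marker the latent value is copied from the
previous marker with probability ld_rho (default 0.7) and redrawn
otherwise; the allele is the indicator u < p. Copying the rank rather
than the allele keeps every marker's marginal frequency exactly at its
subpopulation value — so the MAF spectrum matches its target under any
ld_rho — while adjacent-marker r² rises monotonically with ld_rho. At
the default density and rho this gives mean adjacent r² near 0.2 and
decay to background within a few marker spacings (tens of kb),
matching the LD scale the analysis assumes. Correlation decays per
marker step, not per bp, so unevenly spaced markers have slightly
uneven decay in physical distance; the generator targets bp-scale decay
only and makes no attempt at a cM map.

Phenotypes follow the two-way model above with genetic values
g_i = Σ QTL effects × dosage + iid polygenic term. The polygenic term
is deliberately independent across accessions (not kinship-structured):
that is sufficient for the ANOVA/heritability and marker-panel
experiments, and keeps planted-QTL power analyses interpretable. The
annotation generator places one gene within a configurable offset of
each planted QTL plus Poisson-like random non-overlapping genes, so
candidate-gene reports always have a recoverable truth.

What the generator does *not* emulate: coalescent genealogies,
recombination hotspots, allele-frequency clines beyond two clean
subpopulations, genotyping-error structure, or kinship-correlated
polygenic effects. Tests passing on these simulations therefore
establish the correctness and calibration of the estimators under the
stated models — not robustness to every feature of real panels.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks use deliberately modest sizes chosen as the
smallest that leave the checked effects comfortably resolvable: OLS
collapse at n = 200 × 500 markers; null calibration at n = 200 × 2,000
independent markers (the KS test assumes independent draws, so the
calibration panel is generated without LD) and the structure confound
at n = 300, Fst 0.15; heritability recovery with 150 accessions × 2
years × 3 replicates over 50 seeds; the LD-walk oracle on 100 random
50-marker chromosomes; the GS experiment at n = 300 × 2,000 markers
with five planted QTLs (h² ≈ 0.6) and 100 repetitions per cell. All
randomness is seed-derived and every run is deterministic given its
seed.

## Known limitations

- Method-of-moments ANOVA only; unbalanced trials need an external REML
  fit before using the heritability formula.
- The EMMAX approximation can mis-state p-values slightly for markers
  with very large effects (variance components are not re-estimated per
  marker); use the exact mode when that matters.
- The "contribution (%)" definition is one of several in circulation;
  comparisons across software should rely on p-values, not R².
- Composite (genotype-correlation) r² slightly understates gametic LD
  for loci out of Hardy–Weinberg proportions; block construction uses
  EM gamete frequencies where gametes matter.
- The LD walk inherits the noise of r² estimates near the 0.1
  threshold: borders can shift by a marker between samples of the same
  population.
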