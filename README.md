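# napusgwas

Association mapping and genomic selection for seed-fiber traits in
rapeseed (*Brassica napus*), built for diversity panels of inbred lines
genotyped at tens of thousands of biallelic SNPs and phenotyped in
replicated multi-year trials. The motivating application is
yellow-seeded rapeseed breeding, where seed acid-detergent-lignin (ADL)
content and hull content (HC) serve as screening indices: the package
finds the SNPs associated with these traits, delimits the physical
intervals they tag, lists nearby candidate genes, and quantifies how
much GWAS-informed marker panels improve genomic prediction.

## What it computes

**Phenotypes.** Descriptive statistics (range, mean ± SD, CV%), Pearson
correlations, skewness/kurtosis normality metrics, a grid-search Box–Cox
transformation, and method-of-moments variance components from a
balanced two-way ANOVA (genotype × environment with replicates), giving
broad-sense heritability on an entry-mean basis:

    h² = σ²_g / (σ²_g + σ²_ge/n + σ²_e/(n·r)) × 100%

with *n* environments (years) and *r* replicates.

**Association.** A Q + K mixed linear model: fixed structure covariates
Q (top PCs of the standardized dosage matrix at MAF ≥ 0.2), a VanRaden
genomic relationship matrix K, spectral REML for the variance ratio
δ = σ²_e/σ²_g under the null, and per-marker generalized-least-squares
t-tests with the null covariance held fixed (the P3D/EMMAX
approximation; an exact per-marker REML mode exists for small panels).
Multiple testing uses the rank/step-up rule — select the largest rank
*n* with m·p₍ₙ₎/n ≤ q — which is the Benjamini–Hochberg procedure, at
q = 0.01 by default.

**Intervals.** The R-QTL LD walk: from each significant SNP, step
outward marker by marker; the first flanking SNP with r² < 0.1 against
the lead is accepted as the interval border. Four-gamete haplotype
blocks (two-locus EM haplotype frequencies from unphased genotypes;
MAF ≥ 0.05, genotype rate ≥ 75%, HWE exact p ≥ 0.001) and candidate
genes within ±250 kb of each lead SNP complete the locus reports.

**Genomic selection.** RR-BLUP (y = 1μ + Mu + e, u ~ N(0, σ²_u I)) with
λ = σ²_e/σ²_u by REML, evaluated over 40–80% training fractions and
three marker panels: all markers, markers significant in a GWAS run
inside the training fold only, and equally sized random panels.

**Synthetic data.** A generator emulating the study system — ~520
accessions in two weakly diverged subpopulations (Balding–Nichols
frequencies), ~32k SNPs with Markov-copying LD, replicated two-year
phenotypes with planted QTLs — so the whole pipeline is testable
without the (undeposited) real panel.

## Worked example

```python
import numpy as np
from napusgwas import sim, popgen, association, intervals

cfg = sim.SimConfig(n_samples=200,
                    chromosomes=(("A01", 500, 7_500_000), ("A02", 500, 7_500_000)),
                    fst=0.05, ld_rho=0.7, missing_rate=0.02, seed=1)
panel = sim.simulate_genotypes(cfg)
G, mm = popgen.filter_markers(panel.genotypes, panel.marker_map)

qtl = sim.QTLSpec(mm["id"].iloc[120], effect=0.8)
pheno = sim.simulate_phenotypes(G, mm, [qtl],
                                sim.TraitSimParams(mu=5.0, var_g_poly=0.2,
                                                   var_e=0.2, var_ge=0.1, var_resid=0.3),
                                seed=2)
y = pheno.groupby("accession", observed=True)["value"].mean().reindex(G.samples).to_numpy()

K = popgen.compute_kinship(G)
Q = popgen.structure_pca(G, k=2, seed=0)
res = association.scan(G, y, Q=Q.to_numpy(), K=K.to_numpy(), marker_map=mm)
sel = association.fdr_select(res["p_value"].to_numpy(), q=0.01, ids=res["id"].to_numpy())
print("significant markers:", sel.n_selected, " p threshold:", sel.p_threshold)
for iv in intervals.build_rqtl_set(sel.selected_ids, G, mm):
    print(f"R-QTL {iv.chrom}:{iv.left_border_pos}-{iv.right_border_pos}  {iv.length_kb} kb  leads={iv.lead_ids}")
```

Output:

```
significant markers: 2  p threshold: 1.258548778691519e-05
R-QTL A01:1926502-1955434  28.93 kb  leads=['rs127']
R-QTL A01:1952729-1966099  13.37 kb  leads=['rs128']
```

The scan flags the planted QTL (marker 120 after QC is rs127) and a
map-adjacent linked marker; since the two significant SNPs are adjacent,
each bounds the other's walk and the two determination intervals share
the region between them. The printed p threshold is the largest
selected p-value, so the achieved FDR m·P/n stays below 1%.
The same objects feed `intervals.four_gamete_blocks`,
`intervals.candidate_genes` and `gs.run_gs_experiment`; the
`napusgwas` CLI (`simulate`, `qc`, `pheno`, `gwas`, `rqtl`, `blocks`,
`genes`, `gs`, `all`) wraps the same calls for file-based runs.

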