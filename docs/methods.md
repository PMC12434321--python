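# Methods

`haploscan` re-implements the indirect route to chromosomal-inversion
discovery from low-coverage whole-genome data: genotype likelihoods
throughout, linkage-disequilibrium haploblocks as the primary signal, PCA
karyotyping inside candidate blocks, observed heterozygosity for
orientation and breakpoints, windowed F_ST between population groups,
redundancy analysis against environmental predictors, and mitochondrial
haplotype networks for the colonization-history question. This note
records the models, the defaults and why they sit where they do, and what
the synthetic data do and do not establish.

## Genotype-likelihood model

All analyses run on per-site likelihood triplets L(g), g ∈ {0, 1, 2} copies
of the minor allele. With a symmetric per-read error ε, a read reports the
minor allele with probability (g/2)(1−ε) + (1−g/2)ε, so

    L(g) = [(1−g/2)(1−ε) + (g/2)ε]^n_major · [(1−g/2)ε + (g/2)(1−ε)]^n_minor,

stored normalized (the constant cancels in every likelihood ratio). A site
with zero reads is the uniform triplet — missing, never an error. The het
term is (1/2)^depth regardless of ε, so even error-free reads never fully
exclude heterozygosity at low depth; this is the central fact of ~3×
analysis and the reason hard calls are deferred to the one stage (RDA)
whose downstream machinery requires them.

* `em_maf`: EM under the Hardy–Weinberg prior P(g|f) = Binom(2, f);
  f_{t+1} = (1/2N) Σ_i E[g_i | data_i, f_t]; tolerance 1e-8, ≤200
  iterations (far below any precision reported downstream). The estimand is
  the sample's allele frequency: at N = 100 the population parameter
  differs from it by ~0.03 RMS binomial noise, which no estimator removes.
* `call_snps`: LRT = 2[ℓ(f̂) − ℓ(0)] against χ²(1). The ½-point-mass
  boundary correction is deliberately not applied — matching the common
  upstream implementation — which is conservative (p-values at most double
  their boundary-corrected value). Defaults p < 1e-6, f̂ ≥ 0.05.
* `depth_filter`: per-site total depth within mean ± c·sd (c = 1 by
  default; the published bounds 474–676 around a mean of 575 are a 1-sd
  band) and ≥ min_ind covered individuals.
* `covariance_pca`: posterior dosages ĝ = E[g | data, f̂] under the HWE
  prior, standardized by √(2f̂(1−f̂)) and centered on their **empirical**
  per-site mean. Centering on the model mean 2f̂ instead leaves a rank-one,
  all-positive common mode proportional to the frequency-estimation error
  (SE ≈ 0.02 at N = 120, 3×) that can claim the lead eigenvector and bury
  real structure; empirical centering cancels it identically. Missing
  individuals carry the prior-mean dosage, i.e. ≈ 0 after centering.
* `group_genotype_freq`: unconstrained trinomial EM; H_obs is the
  heterozygote class. With hard calls it reduces to counting.

## LD, haploblocks

`pair_r2_em` runs the classic two-locus haplotype-frequency EM for unphased
data, generalized to likelihoods: each individual contributes the product
of its two triplets over the 9 two-locus genotypes; random union of
gametes; tolerance 1e-8, ≤500 iterations. r² = D²/(f₁(1−f₁)f₂(1−f₂)).
Either locus monomorphic under the fitted frequencies ⇒ r² reported 0 with
a flag.

The heatmap statistic is a per-window-pair quantile of SNP-pair r² in
250 kb windows. The published figure's "second percentile" is ambiguous
between the 2nd and 98th percentile; the default is q = 0.98 — a high
quantile is what makes a block of elevated LD visible against a noisy
background — and q is a parameter. SNPs are subsampled at 50% (seeded),
and within each window pair at most 36 SNP pairs are drawn for the EM
kernel; a quantile of an (approximately) exchangeable set is insensitive
to this cap, which bounds the kernel cost at desk scale.

Blocks are called by a density-of-exceedance square-growing scan: binarize
cells at r² ≥ 0.6 (the threshold the source heatmaps used), grow [start,
end] while ≥ 60% of non-missing cells with window separation ≥ 2 are ON
(and ≥ 50% of cells are non-missing), then trim edge windows whose own
cross-column falls below the density — greedy growth otherwise smears a
sharp edge by several windows. Spans below min_span (1 Mb default; 10 Mb
at study scale) are dropped; overlapping intervals merge. The published
analysis delimited blocks visually; this scan is the reproducible stand-in,
with every threshold exposed.

LD decay is fit as r²(d) = r²₀·e^(−d/τ) + c on 1 kb-binned means
(half-decay distance τ·ln 2); pruning deletes, repeatedly, the site with
the largest incident r²-weight sum among edges with r² ≥ 0.4 within 15 kb,
ties broken toward the lower genomic position for determinism.

## Karyotyping and orientation

PC1 of the within-block covariance separates the three arrangement
genotypes; clustering is **exact 1-D 3-means by dynamic programming** —
deterministic and globally optimal with no initialization. A
percentile-initialized Lloyd iteration was considered and rejected: with
one homokaryotype group at a few percent of the sample (the regime the
source system actually shows, ≤ 8 of 192 individuals), the 10/50/90
percentile seeds all land inside the majority cluster and the iteration
splits it. The three-groups gate is mean silhouette ≥ 0.70: an optimal
1-D split of pure Gaussian noise already scores ≈ 0.56, real karyotype
structure ≥ ~0.9 in every scenario tested. The threshold is a parameter.

Orientation assumes the lower block-wide H_obs homokaryotype carries the
derived (inverted) arrangement — an assumption inherited from the source
reasoning and flagged as such in the output; the call is "ambiguous" when
the homokaryotype means differ by less than 0.02. Breakpoint refinement
takes the maximal run of 10 kb windows, seeded at the LD block, where
H_obs(het) − H_obs(inverted hom) > 0.02; the het-minus-inverted contrast
is used rather than raw low H_obs because low-MAF runs also depress raw
H_obs. Runs may bridge up to 2 consecutive below-margin windows and
windows without SNPs are skipped: at desk-scale site density a single
noisy 10 kb window would otherwise truncate the interval.

## F_ST

Sample-allele-frequency (SAF) vectors come from the standard dynamic
program over individuals with hypergeometric allocation weights; the joint
spectrum Φ(j,k) is EM-estimated (uniform start, tolerance 1e-9) and
optionally folded by merging (j,k) with (2N₁−j, 2N₂−k). Per-site Reynolds
(1983) variance components α, β are posterior expectations over (j,k);
when Φ is folded its mass is split over both orbit members first — α and β
are orbit-invariant, and without the split the posterior cannot follow
data lying on the non-representative side of the fold. The Reynolds
weights use diploid sample sizes with frequencies from 2N alleles; under
equal population frequencies E[α] = 0 exactly. Windowed F_ST is the ratio
of sums in 10 kb/10 kb windows anchored at 0, last partial window kept,
< 5 usable sites flagged. A Hudson-type estimator is deliberately not
implemented; the truth-count oracle in the tests uses the same Reynolds
grids so that implementation and oracle disagree only through the
GL → SAF → posterior path.

## Redundancy analysis

Hard calls are argmax-likelihood genotypes gated on per-individual depth
∈ [2, 5] (ties missing); SNPs with call rate < 0.90 or called-MAF < 0.10
are dropped and remaining gaps take the modal genotype (ties → lower
value, for determinism). Y is the column-centered genotype matrix (a
scale flag exists, off by default, the common RDA convention); X the
standardized environment, screened at pairwise |r| < 0.70. The fit is the
SVD of X(XᵀX)⁻¹XᵀY; R² = ‖Ŷ‖²/‖Y‖²; adjusted R² is the Ezekiel
correction. Significance: permutation of predictor rows, pseudo-F, p =
(1 + #{F* ≥ F})/(1 + n_perm), default n_perm = 999, seeded; per-axis tests
peel preceding axes off Y and compare the leading squared singular value.
Outliers are SNPs whose loading lies > 3 SD from that axis's mean, unioned
across axes (a pooled switch exists); a zero-SD axis flags nothing.
Individuals inherit their deme's environmental values — streams were
measured, not fish — so the pseudo-replication of the source design is
reproduced, not repaired.

## Mitochondrial networks

Identical sequences collapse to haplotypes after alignment-wide removal of
any column with a gap or ambiguity (deterministic Hamming distances; the
source's treatment is unstated). The median-joining network (ε = 0) is
the union-of-MSTs minimum spanning network over the observed haplotypes
plus the set of column-majority quasi-median vectors that minimizes the
spanning cost. When the quasi-median closure is small (≤ 14 candidates,
computed on variant columns only) that minimizing subset is found exactly
by subset search — a stepwise heuristic provably misses jointly-paying
median pairs on a few percent of small random instances — and a greedy
one-median-per-pass ascent (ties: lexicographically smallest sequence)
takes over beyond the cap, followed in both cases by pruning of medians
that no longer pay for themselves. On additive (tree-metric) haplotype
sets no median reduces cost and the network is the MST. Neighbor joining is the
canonical Q-matrix agglomeration, ties toward the lowest index pair;
bootstrap resamples alignment columns (default 1,000 replicates; the
source's 100,000 is supported but not a test default), support = fraction
of replicates containing the bipartition; output is rooted on the
outgroup. The carrier test reports how many haplotypes contain inversion
carriers, how many of those are shared with non-carriers, and a monophyly
proxy: TRUE only if all carrier haplotypes are carrier-exclusive and
connected through at most median nodes.

## The synthetic cohort

The generator is a founder-mosaic model, not a coalescent: standard (STD)
haplotypes are mosaics of a small founder pool (8 by default) with
Poisson breakpoints; two sites at distance d share a founder segment with
probability e^(−λd), giving r² an e-folding scale of 1/(2λ) — the default
rate reproduces the 15 kb decay scale. Deme-specific Dirichlet founder
weights (concentration 1.0) create drift-level background differentiation
(genome-wide F_ST of roughly 0.05–0.15, matching the strongly structured
study system); `None` gives a panmictic pool. The inverted (INV)
arrangement descends from a single founder plus private marker mutations
inside the interval; heterokaryotype recombination is rejected outright
inside the interval (no gene flux) and free outside it. Consequences, by
construction: INV/INV individuals have H_obs ≈ 0 inside the interval (the
derived arrangement carries no diversity), heterokaryotypes are
heterozygous at every marker, and marker pairs are in complete LD.

Private-marker density defaults to ~30% of sites inside the interval
(2,500 markers in the 18 Mb default interval). Much sparser derived
variation leaves the 250 kb, 98th-percentile heatmap cells without
diagnostic pairs and no block is callable even from noise-free genotypes;
the dense regime is the one in which the source heatmaps show r² > 0.6
blocks. Site density defaults to 0.5 SNP/kb (20,000 sites on 40 Mb) — a
deliberate desk-scale choice that keeps the full pipeline at minutes on
one CPU while leaving ≥ ~5 SNPs per 10 kb H_obs window; the source data
are ~1 SNP/kb genome-wide.

Read depth is Poisson (3× default), reads err symmetrically with ε = 0.01,
and the GL triplets are produced by the same likelihood model the analysis
uses — so the generator tests the pipeline's statistics, not robustness to
model misspecification. Environmental covariates are deme-level:
base + effect·(deme INV frequency) + Gaussian noise, with couplings
(+3 °C, −0.4 pH, −0.5 flow) per unit frequency so inversion demes run
warmer and slower; noise is redrawn (≤ 100 attempts) until all pairwise
|r| < 0.70. Mitochondrial haplotypes are a star: each of H−1 haplotypes
differs from a central one by 1–7 substitutions at globally distinct
positions (pairwise distances are sums of steps), membership follows a
harmonic frequency profile (one dominant haplotype, a long rare tail), and
at least two haplotypes are forced to contain both carriers and
non-carriers when both exist.

What passing tests therefore show: the estimators recover the quantities
their own models define, at the stated depths and sample sizes, and the
end-to-end chain finds a planted inversion under the generator's
assumptions. What they do not show: robustness to mapping artifacts,
base-quality miscalibration, reference bias, gene flux/double crossovers
inside inversions, non-equilibrium demography, or selection — none of
which the generator emulates.

## Numerical conventions

Positions are 1-based in site tables and BEAGLE markers, 0-based half-open
in BED and all internal intervals; conversion lives in `gtio` only. All
randomness flows from one seeded `numpy` Generator per entry point;
fixed seed ⇒ byte-identical outputs. EM tolerances: 1e-8 (MAF, trinomial,
two-locus), 1e-9 (SFS). Ties everywhere break deterministically (lowest
position, lowest index, lexicographic smallest). Degenerate inputs:
all-zero triplets are rejected at IO; zero-depth individuals are uniform
triplets; monomorphic sites are excluded from PCA with a warning; an LD
decay fit with flat profile is flagged rather than extrapolated.

## Known limitations

The block caller's thresholds (0.6/0.6) were chosen for contrast with the
published r² ≈ 0.6 visual criterion, not calibrated for false-discovery
rate; single-deme fixation of a neutral haplotype could mimic a block.
Inversion status remains indirect: LD + karyotype + H_obs evidence cannot
distinguish inversions from fusions or other recombination-suppressing
haploblocks, and no attempt is made to. The RDA inherits the source
design's pseudo-replication (individuals share stream-level covariates),
so its p-values describe that design, not independent sampling.
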