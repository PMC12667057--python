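# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical decisions a user may want to audit.

## Population simulator

Meiosis uses a no-interference model: per chromosome, the crossover count
is Poisson with mean equal to the genetic length in Morgans and crossover
positions are uniform on the physical length, with a fair-coin starting
phase. Interference would sharpen breakpoint spacing but is not needed to
exercise the bin caller, so the simplest standard model is used. There is
no obligate chiasma.

A population is founded from two fully divergent inbred parents: the F1 is
heterozygous genome-wide, each line is founded by one selfing of the F1
(its F2 individual) and advanced by `selfing_generations` further rounds of
single-seed descent. `selfing_generations` therefore counts rounds *after*
the F2, and residual heterozygosity after g rounds is (1/2)^(g+1) in
expectation — the default g = 9 gives an F10-equivalent population at
(1/2)¹⁰ ≈ 0.098%.

Genotyping noise is applied only to the observed matrix (truth is retained
unperturbed): each call is flipped to one of the two other states with
equal probability at rate `genotyping_error_rate` (a symmetric model — the
error process of real variant calling is not specified in enough detail to
justify anything more structured, and the 9-of-15 majority rule is designed
to absorb symmetric noise) and set missing at rate `missing_rate`.

Default genome: 12 chromosomes × 5 Mb × 1 Morgan at 200 SNPs/Mb (12,000
SNPs). This preserves the chromosome count and the roughly 1-Morgan scale
of a pepper genome at desk scale; SNP density is far below a real
resequencing panel, which mainly coarsens breakpoint resolution (~5 kb
between SNPs).

Quantitative phenotypes are y = Σ a_q·x_q + ε with x_q the 0/1/2 B-allele
dosage at each placement; the noise variance is scaled so the genetic
fraction of variance equals the trait's target PVE given the realized
genetic variance in the population. Replicates share genetic values and
draw independent noise. The AND-epistatic binary trait is 1 iff the line is
homozygous for the A parent at both placements, with no observation noise —
a presence/absence trait like pungency. F2 bulk phenotypes use a single
plant value (one-season F2 screen, no replicates).

Expression trajectories: each gene is one of four archetypes
(growth-tracking, flat, declining, late-peaking). The growth-tracking shape
is an affine map of the growth-rate vector (so a noiseless growth gene
correlates perfectly with growth rate); trajectories are the shape times a
log-normal gene abundance (median ≈ 7 FPKM) times per-observation
log-normal noise (σ = 0.2 on the log scale, about ±20%, typical of
replicate-level FPKM scatter). Three replicates per stage; five stages by
default with a logistic fruit-length curve supplying the growth rate.

What the simulator does **not** emulate: read-level artifacts (mapping
error, allele-specific bias), segregation distortion, residual
heterozygosity hotspots, linked selection during line advancement,
structural variants, and expression count noise (FPKM noise is log-normal,
not negative-binomial). Tests passing on simulated data therefore validate
the algorithms under clean statistical assumptions, not robustness to every
artifact of real data.

## Bin map construction

Windows of 15 SNPs (step 1) are called AA/BB/HET when at least 9 SNPs agree;
missing SNPs count toward the window but match no state; windows with no
majority are *unavailable*. Since 9 > 15/2 at most one state can qualify.
The window-to-SNP projection is a per-SNP majority vote over covering
windows' called states, with ties or no called cover giving NA — a
deterministic, order-independent rule consistent with bins being runs of
SNPs sharing a parental genotype.

Runs are maximal stretches of identical non-missing SNP calls (missing
calls are transparent and never imputed). Bin span is first-SNP-to-last-SNP
inclusive (length = end − start + 1); runs spanning less than 250,000 bp
are dropped and their span becomes missing — exactly 250,000 bp is
retained; removed spans are *not* merged into a neighbour, since merging
would invent genotype. Breakpoint intervals are recorded between
consecutive runs *before* the length filter: a short run removed by the
filter still marks two real crossovers, and discarding its boundaries was
measured (on the default simulated genome) to cost about ten points of
crossover recall, because double-crossover segments shorter than 250 kb are
common at 1 Morgan per 5 Mb. The breakpoint point estimate is the interval
midpoint — unbiased under uniform crossover placement within the
uninformative gap.

Population bins are the partition induced by pooled breakpoint midpoints;
a line's genotype in a population bin is the unique genotype among its
overlapping retained bins (none or mixed → NA). Homozygosity is
bp-weighted over the non-NA genome. Because the per-line "recombination
frequency" statistic has several plausible definitions, three are emitted
(breakpoint count, minor-parent fraction, per-boundary switch rate) and
none is privileged; both population-bin and line-bin counts are reported.

## Mixed-model association

Kinship is the centered cross-product K = ZZᵀ/c over mean-imputed,
unit-variance-scaled polymorphic bin dosages, so the diagonal averages
about 1. The REML criterion for δ = σ²_e/σ²_g is profiled on the
eigendecomposition of K, minimized on a 41-point log grid spanning 1e−5 to
1e5 and refined by bounded Brent in log space (xatol 1e−10). Per-bin tests
fix δ at the null estimate (EMMAX/P3D); the per-bin residual variance is
re-estimated, so with K = I the scan reduces *exactly* to ordinary least
squares. Wald p-values use the χ²₁ reference for (β̂/se)²; with ~200 lines
the difference from the t reference is negligible. Missing dosages are
mean-imputed per bin; lines missing a phenotype are dropped per trait;
replicate phenotype columns are averaged per line before association.
Binary traits are analyzed as 0/1 responses in the same framework.

The default genome-wide threshold is Bonferroni at α = 0.05 over testable
(polymorphic) bins — conservative, with a permutation alternative (5%
quantile of the genome-wide minimum p over phenotype permutations).
Significant bins within 2 Mb on a chromosome merge into one locus; PVE =
β̂²·Var(x)/Var(y) at the lead bin with β̂ from the GLS fit, clamped to
[0, 1]. Per-trait summaries take the maximum PVE over that trait's loci.

Calibration note: the null-uniformity check of the scan uses a panel of
2,000 *unlinked* synthetic bin dosages, because the Kolmogorov–Smirnov
reference distribution assumes independent draws; p-values at physically
linked bins are individually uniform but strongly dependent, which breaks
the KS critical value, not the test statistic being checked. Power and PVE
recovery are validated on fully linked simulated genomes.

## ΔSNP-index BSA

The statistic is the classic per-bulk SNP-index (alt/total) and its
high-minus-low difference, averaged in 1-Mb windows stepping 100 kb, with
SNPs below 10× depth in either bulk masked. Significance comes from a
Monte Carlo null: with no linkage a bulk of b individuals carries 2b
chromosomes, so its allele frequency is Binomial(2b, ½)/2b; depths are
resampled from the observed depth distribution and Δ is recomputed per
replicate (500 by default, minimum 100). Per-window two-sided 95% and 99%
quantiles form the envelopes; maximal runs of windows outside the 95%
envelope are candidate regions, reported 1-based inclusive with the
max-|Δ| window as peak. This is a deliberate, fully specified substitute
for black-box BSA software: the plotted quantity is the standard
SNP-index, and the null construction is stated above. Bulk size has no
literature default here and is a required parameter.

## Co-expression filtering

BH adjustment is the step-up rule (delegated to statsmodels). The DEG rule
is: stage-mean FPKM > 1 in at least one stage, some stage-pair fold change
> 1.5 or < 0.67 (computed on stage means with a 0.1-FPKM pseudocount to
avoid division by zero), and BH-adjusted p < 0.05. "Stage" plays the role
of tissue because the design is one tissue over developmental stages. The
differential test itself is consumed as a raw p-value column, not
re-implemented.

Clustering is K-means on per-gene z-scored stage-mean trajectories
(multiple restarts, best inertia, seed-deterministic); k defaults to 6 and
is a config knob. Genes with zero stage variance standardize to the zero
vector. Note that once standardized, a truly flat noisy gene is an
isotropic random vector and *cannot* be recovered by any trajectory
clustering; in practice (and in the validation tests) clustering receives
variability-screened genes, on which archetype recovery is near-perfect.
The growth rate is the forward finite difference of fruit length assigned
to the right-hand stage (a vector over stages 2..S); the selected cluster
maximizes the Pearson correlation of its centroid with that vector, and
all cluster correlations are reported so a low best-correlation is
visible. TFs among the selected cluster's members are dropped below a
mean FPKM of 2 and counted by family.

## Trait–locus network

Lines heterozygous or missing at either locus are excluded from two-locus
haplotype counts (at ~99.9% homozygosity this loses almost nothing;
half-weighting heterozygotes would change results only in early
generations). D′ uses the standard normalization by D_max with the sign
convention split on D > 0 / D < 0 and D = 0 ⇒ D′ = 0. LD between loci is
computed from their lead bins' dosage vectors. Locus weights are half-up
rounded −log₁₀ p (so p = 3.43e−13 → 12). In the connectivity formula the
denominator runs over the trait's full locus set L(·) — the only reading
under which the ratio is informative — and a locus shared by both traits
counts toward C(A,B) alongside LD-mediated connections. LD edges require
D′ strictly above the threshold (default 0.8); the r² edge-class cut
(default 0.5) is cosmetic metadata on edges. Graphs are exported as
GraphML plus two edge-list TSVs; layout is left to viewers.

## Problem sizes used in validation

The test suite validates at desk scale, chosen to keep the full run within
a few minutes: 216-line populations on the default genome for
homozygosity, power (200 replicates over three independent populations
with fresh phenotypes and random QTL placements per replicate — phenotype
noise and placement are the randomness that drives power, so populations
are reused across replicates) and PVE recovery (200 replicates); 200 lines
for crossover recovery; 2,000 markers × 50 traits for null calibration;
500 null data sets (one 5-Mb chromosome, 250 SNPs, depth 60) for BSA
envelope calibration and 100 simulated F2 bulk experiments (12
chromosomes, 50 SNPs/Mb, 10% bulks, depth 60) for BSA recovery; 1,000
random inputs for the exact window-caller, LD and BH oracles.

## Known limitations

- The bin caller cannot see double crossovers spanning fewer than ~9 SNPs
  (~45 kb at default density); their junctions are absent from the bin map
  (measured recall ≈ 94% at 150-kb tolerance, precision ≈ 100%).
- P3D shares one δ across bins; a marker carrying a large fraction of the
  kinship signal is conservatively shrunk (the `exact` flag re-fits per
  bin).
- PVE at the lead bin inherits winner's-curse upward bias at high power and
  attenuation from imperfect bin-QTL correlation; at PVE 0.3 and n = 216
  these nearly cancel (mean estimate ≈ 0.31).
- The BSA null assumes bulks drawn from an unselected F2 at 1:1
  segregation; segregation distortion would mis-calibrate envelopes
  genome-wide.
- NC depends on the locus-calling threshold upstream: loci missed by the
  scan cannot contribute shared signal.
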