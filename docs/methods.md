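# Methods

This note documents the models, conventions and numerical choices behind
`methylcross`, and what the synthetic generator does and does not emulate.

## Methylation quantification

**Contexts.** Every cytosine (C on the plus strand, G on the minus strand)
is labelled from the 3-base window read 5'→3' on its own strand: CG if the
next base is G, CHG if the base after next is G, CHH otherwise (H = A/C/T).
Windows truncated by a contig end default to CHH unless the CG call is
already decided by the next base; windows containing a non-ACGT character
are skipped and counted in the log.  This affects at most two positions per
contig end and is the conservative choice (CHH is the residual class).

**Weighted levels.** A feature's methylation per context is
`Σ count_meth / Σ (count_meth + count_unmeth)` over its cytosines of that
context, both strands pooled regardless of feature strand (CG and CHG
methylation are strand-symmetric, and the analysis does not stratify by
strand).  Only positions sequenced at least 3× enter (configurable).
Pooling counts rather than averaging per-position fractions weights each
position by its coverage; the quantity is invariant to splitting a
position's counts across records.

**Inclusion rule.** A feature enters comparisons when ≥ 25 % of its
cytosine positions (any context, from the genome) pass the coverage floor.
The package consumes call tables, not alignments, so "covered in 25 % of
the length" is operationalised at cytosine-position resolution — the
closest observable proxy; the fraction is computed per feature, pooled over
contexts, because inclusion is a property of the feature, not of a context.

**Conversion rate.** Estimated as `Σ unmethylated / Σ all calls` on the
chloroplast contig, which is biologically unmethylated; residual C calls
measure conversion failure.  The observed methylation of a position with
true level m is therefore `m + (1 − m)(1 − conversion)` and all recovery
tests compare against this conversion-adjusted expectation.

**Class comparisons.** Genotype comparisons per TE class use the unpaired
two-sided Wilcoxon rank-sum test over features included in both genotypes
(features are not strictly paired across references), with the mean
difference reported in percentage points as hybrid-minus-parent.  Identical
inputs short-circuit to p = 1.

## DMR calling

Windows are adjacent 50-bp tiles (window = step; the final partial tile is
tested like any other, since dropping it would silently ignore chromosome
ends).  Counts are pooled over cytosine positions covered in **both**
conditions; the per-window test is two-sided Fisher's exact on
`(meth, unmeth) × (condition A, condition B)`.

The Fisher p-value is computed in-package: for tables with grand total
≤ 500, exact integer hypergeometric enumeration (the returned double is the
correctly rounded value of an exact rational); larger tables use a
log-gamma tail sum with a 1e−7 relative tie tolerance.  The exact path
makes the p-value bit-reproducible and independent of any library's tie
conventions; tests cross-check it against both an independent
`Fraction`-arithmetic enumeration and `scipy.stats.fisher_exact`.

Filters (applied before multiple testing): ≥ 3 cytosines of the context
with data in both conditions, absolute proportion difference ≥ 0.25, and
mean total reads per cytosine (averaged over the two conditions) ≥ 8.
Benjamini–Hochberg runs per context across the filtered windows; the FDR
cutoff defaults to 0.05 and is exposed as a parameter.  Significant windows
become candidate bins; bins of the same context and direction separated by
an inter-bin gap < 300 bp are merged (a 300-bp gap stays split).  Merging
opposite directions would leave the DMR's direction undefined, so
directions are processed independently; merged means are weighted by the
number of member windows, which makes merging idempotent.  DMR direction is
assigned per merged region, whose member windows are direction-homogeneous
by construction.

Replicate handling: condition counts are pooled before the 2×2 test — a
single Fisher test per window implies pooling.  Annotation assigns a DMR to
every region category (LTR retrotransposon, gene body ATG→stop including
introns, 1-kb upstream of the ATG) it overlaps by ≥ 1 bp, so one DMR can
count in several rows; per-family summaries keep families with ≥ 5 DMRs.

## Expression analysis

**Normalization** is median-of-ratios: per-feature geometric-mean reference
over features positive in all samples, per-sample size factor = median of
ratios; if no feature is positive everywhere it falls back to total-count
scaling (logged).  `log2(normalized + 1)` is the heatmap-ready measure — a
deliberate approximation of regularized-log values, which are
package-specific.

**Testing.** Per feature and per contrast, a negative-binomial Wald-type
test: `log2FC = log2((μ_b + ½)/(μ_a + ½))` on normalized group means, with
variance `μ + αμ²`.  The dispersion α is a per-feature method-of-moments
estimate shrunk geometrically (weight 1:1 in log space) toward a fitted
trend `α(μ) = a₁ + a₀/μ`.  The trend is fitted by least squares to the
*unclipped* moment estimates — negative estimates are informative about
small dispersions, and flooring them before the fit would bias the
intercept upward and cost power.  The statistic is referred to a Student-t
with `df = (n_a + n_b − 2) · 2`: shrinking each observed dispersion (4
residual df at n = 3) toward the trend with equal weight borrows an equal
number of prior df, the moderated-t construction.  At n = 3 per group this
choice is near-exactly calibrated in simulation (null p < 0.05 fraction
≈ 0.05) where a plain normal reference is anticonservative and the
unmoderated t is conservative and underpowered.  Significance requires BH
q < 0.05 **and** |log2FC| ≥ 1; both thresholds are parameters.

**Pattern classification.** The three pairwise calls (A-vs-P, A-vs-H,
P-vs-H) form a relation triad; the 13 weak orders of three items map
one-to-one onto the consistent triads, yielding fine patterns written with
A's group first (`A>H>P`, `(A=H)>P`, `A<(H=P)`, `A=H=P`).  The 14
inconsistent triads — possible with thresholded tests — are classed by the
parental A-vs-P contrast, which anchors the category scheme, with H placed
with the parent whose contrast against H carries the weaker evidence
(larger p); such calls carry `consistent = False` and keep their fine
pattern string so any regrouping is lossless.  Coarse classes: hybrid_up /
hybrid_down iff H is significantly above / below both parents, else
peach_up / almond_up by the parental contrast, else equal.

**Expression floor.** "Expressed in at least one genotype" means mean
normalized count ≥ 5 in some genotype (configurable); some floor is needed
to define the denominator of the category percentages, and 5 normalized
counts is a conventional low-expression cutoff.

**Representatives and orthologs.** A family representative is the
highest-coverage genomic copy for the family's assembled contig, subject to
80 % (retrotransposons) / 40 % (DNA transposons) length-coverage cutoffs.
Cross-reference agreement is the Pearson correlation of per-feature mean
log2-normalized expression over ortholog pairs (≥ 3 pairs required).

**qPCR.** ΔCt = Ct_target − mean(Ct of reference genes) per sample;
ΔΔCt = mean ΔCt per genotype minus the calibrator genotype's mean;
relative level = 2^−ΔΔCt, with the replicate SD of ΔCt propagated to the
linear scale (`rel · ln2 · sd`).  The quantity is invariant to a constant
plate offset.

## Synthetic generator

The generator emulates the study's statistical structure, not its biology:

- **Genomes.** One ancestral sequence (default 400 kb, GC 0.38); each
  parent substitutes sites independently with probability `divergence/2`
  (uniform alternative base).  The expected pairwise difference is
  `2q(1−q) + (2/3)q²` ≈ 19.87 SNPs/kb at the default 0.02 — inside the
  ±1 SNPs/kb recovery band; the simpler per-lineage rate was preferred over
  solving the quadratic exactly.  No indels, so both parental coordinate
  systems align 1:1 and one annotation and one spike list serve both
  references.  A separate chloroplast contig (15 kb) is shared by all
  genotypes and fully unmethylated.
- **Features.** TE copies of the four classes (LTR retrotransposon, LINE,
  MITE, TIR; class-typical length ranges) and genes (ATG→stop span) are
  placed by exact free-gap sampling — uniform over all admissible start
  positions — with 1 kb of clearance on each gene's 5' side so the derived
  upstream region is feature-free.  Families are distributed within classes
  with truncated-geometric sizes (a few large families dominate, as in real
  TE censuses).
- **Methylomes.** Feature-level true methylation per (feature, context,
  genotype) ~ Beta(mν, (1−m)ν) around the context means (defaults CG 0.90,
  CHG 0.60, CHH 0.15; concentrations 40/15/15); degenerate means 0 and 1
  are point masses.  Background positions sit at the context mean.
  Coverage ~ Poisson(20); methylated counts ~ Binomial(coverage, p_obs)
  with conversion failure folded in.  The hybrid on each reference is the
  50:50 allelic mixture of the parental feature states — the quantity the
  hybrid-on-parental-reference mapping estimates — bypassing alignment,
  which is out of scope.
- **Spiked DMRs.** Disjoint intervals (default 8 × 200 bp) aligned to the
  50-bp window grid, cycling over LTR copies, genes, upstream regions and
  background, contexts cycling CG/CHG (a CHH shift of the default size
  would be clipped away).  Candidates are accepted only when every covered
  window holds ≥ 3 cytosines of the spiked context — the regime in which
  the window test's own cytosine filter can see the signal.  The spiked
  hybrid level is placed `delta` beyond the more extreme parental level
  (clipped to [0.02, 0.98]) so the realised hybrid-versus-parent contrast
  is at least `delta` wherever clipping permits; direction is forced to
  hypomethylation when the context mean leaves no upward headroom.
- **Counts.** Genes plus one representative per TE family; baseline means
  lognormal around 100; pattern classes drawn from the configured mix
  (defaults 78.3/10.7/10.0/0.7/0.3 %), with genotype means encoding the
  pattern at `lfc_effect = 2` (the "up" parent at 2^lfc, the hybrid
  intermediate at 2^(lfc/2)); size factors lognormal (sd 0.15);
  counts ~ NB(α = 0.05), three replicates per genotype.  A 5 % unexpressed
  fraction exercises the expression floor.  With `lfc_effect = 0` the truth
  is recorded as all-equal, since a zero effect erases every pattern.
- **qPCR.** Ct = 30 − log2(expression) + N(0, sd); reference genes are
  constant across genotypes by construction.

What the generator does **not** emulate: read-level data and alignment
artifacts (mapping bias of hybrid reads, multi-mapping TEs), indels and
structural variation, LINE-like bimodal methylation (a concentration
toggle exists but is off — no parameters are reported for it), TE
transposition, and correlated methylation along chromosomes outside
features.  Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated generative model, not
robustness to alignment artifacts in real bisulfite data.

## Reproducibility and problem sizes

Every stochastic step derives its stream from one seed
(`numpy.random.default_rng([seed, stream])`), and all outputs — including
gzip-compressed call tables, written with a fixed header mtime and empty
filename field — are byte-reproducible.  The pipeline manifest records
per-stage output checksums; stages are recomputed deterministically and
flagged `unchanged_from_previous` when checksums match the prior run.

Default test and acceptance problem sizes (400-kb genomes at 20× coverage,
1 Mb for the SNP-density check, 10,000 windows for the null-DMR check,
~400 features for pattern recovery) were chosen so that each recovery
quantity's Monte-Carlo error is several times smaller than its acceptance
band.

Known limitations: the window test supports adjacent tiles only
(window = step), as in the reference procedure; the NB engine tests one
pairwise contrast at a time rather than a joint GLM; the inconsistent-triad
resolution is a convention, flagged per call rather than hidden.
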