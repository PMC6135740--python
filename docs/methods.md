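# Methods

This note documents the models, conventions and design choices behind
`rainbowseq`, in the spirit of a statistical methods appendix.

## Coordinates and formats

All intervals in memory are 0-based half-open. GTF and RepeatMasker `.out`
records (1-based closed on disk) are converted once, at read time, in
`rainbowseq.io`; writers convert back. No interval with `end ≤ start`
survives any reader — this is asserted by construction in the domain types.
TSV is the exchange format for matrices and metadata; spliced reads may
come from BED12 or BAM/SAM, where CIGAR `N` gaps split aligned blocks and
deletions do not. Repeat strand is recorded but ignored in overlap tests.

## Lineage assignment

A cell's marker is called when one marker's construct-mapped read count is
≥ `min_reads` (default 10) and ≥ 5× every other marker's count. The
thresholds guard against ambient contamination and index hopping; both are
exposed on the CLI because the appropriate floor depends on depth. Within
an embryo, exactly two distinct called markers are required; cells with the
alphabetically smaller marker become lineage A. The A/B labels carry no
biological meaning across embryos — the convention only makes runs
reproducible. Embryos showing fewer or more than two markers are entirely
unresolved: with four equiprobable colors per lineage, about a quarter of
embryos are expected to draw the same color twice and be untraceable.

QC keeps cells with ≥ 3,000,000 uniquely mapped read pairs (inclusive at
the boundary). A gene is expressed in a cell iff FPKM is strictly > 1.

## Blastocyst balance

Per marker (GFP, RFP — the imaginable channels when one channel is needed
for nuclear staining), the 2×2 table marker±  × embryonic/abembryonic pole
gives OR = (pos_emb·neg_abem)/(neg_emb·pos_abem). Zero cells get the
Haldane–Anscombe +0.5 on all four cells, keeping the OR finite and the
classification defined. Balanced means strictly 1/3 < OR < 3; an embryo is
unbalanced if any evaluated marker is. Three counting methods: include
embryos with ≥1/3 of cells marker+, ≥1/2, or include all embryos and use
the marker+ pole-count ratio n1/n2 (0.5 added to both counts when either
is 0). The inclusion denominator is all cells of the embryo; percentages
are reported as truncated integers (8/12 → 66).

## Nested variance partitioning

y = log2(FPKM + 1). The model is a Gaussian two-stage nested ANOVA: embryo
as a factor, lineage nested within embryo (A/B labels are arbitrary per
embryo, so a crossed lineage factor would be meaningless). Sequential
(type-I) sums of squares with embryo entered first:

    SS_embryo  = Σ_i n_i (ȳ_i − ȳ)²
    SS_lineage = Σ_i Σ_j n_ij (ȳ_ij − ȳ_i)²
    SS_resid   = Σ (y − ȳ_ij)²

and r = SS_lineage/(SS_lineage + SS_embryo), undefined (and excluded from
R) when the denominator is 0. The decomposition is verified against
statsmodels' type-I `anova_lm` and against direct group-mean sums in the
tests; SS conservation holds to 1e-8 relative tolerance.

With E embryos in a balanced design and no true effects, SS_lineage and
SS_embryo are independent σ²·χ² variables with E and E−1 df, so
r ~ Beta(E/2, (E−1)/2) — for E = 9, Beta(4.5, 4). This closed form is the
null-calibration oracle: 10,000 simulated null genes give KS ≈ 0.005–0.013
against it. The Beta reference set for the qualitative tail comparison
defaults to β(1,3), β(2,2), β(5,5) and is configurable.

The per-feature lineage test is F = (SS_lineage/d1)/(SS_resid/d_res) with
d1 = E and d_res = N − 2E. Features that are constant, or designs with one
cell per embryo-lineage (d_res = 0), are skipped.

## q-values and the shuffled background

q-values are Benjamini–Hochberg by default; a Storey variant
(π0 = min(1, 2·mean(p > 0.5)) scaling) is available. The background
permutes lineage labels *within* each embryo — an unconstrained shuffle
could move embryo effects into the lineage term and invalidate the null —
and reruns the identical ANOVA + q pipeline; multiple shuffles pool their
q ensembles (default 1). Real and background ensembles are compared by
two-sample KS plus counts below q* = 0.01. KS p-values below 2.2e-16 are
reported at that floor.

A calibration caveat discovered while validating this module: under a
global null, BH maps the p vector onto a narrow band just below 1 whose
exact location fluctuates between ensembles, so a two-sample KS on two
*null* q ensembles is large with high probability. The q-scale comparison
is therefore informative only in the presence of signal (where low
q-values dominate the statistic); calibration checks use the p-value
ensembles (`shuffle_background(..., statistic="p")`), which are uniform
and match between real and shuffled labels.

## TRENI calling

Novelty: a multi-exon transcript is novel iff its ordered intron chain
does not occur as a contiguous run in any reference transcript sharing
exonic sequence; monoexonic transcripts are novel iff not contained in a
reference exon. This approximates assembler novel classes without
re-running assembly (out of scope). Novel isoforms are attributed to the
reference gene with maximal exonic overlap.

"Contains a transposon" is operationalized as summed exonic overlap ≥ 10 bp
with a RepeatMasker copy (threshold exposed). Placement is per repeat and
strand-aware: overlap bases strictly 5′ of the start codon are 5′UTR, bases
at/3′ of it are downstream, straddling repeats count in both — so the two
categories need not partition the TRENI set. Per-repeat copies are the
accounting unit (an isoform may carry several repeats).

Junction ratio: denominator = reads overlapping the repeat by ≥1 bp;
numerator = the spliced subset with one block on the repeat and another on
the nearest reference exon of the host gene (minimal genomic gap; ties go
to the 3′-ward exon in transcript orientation). High-confidence repeats
have JR ≥ 0.9 (inclusive).

Family enrichment: per family, the 2×2 table of genome-wide copies
{family vs rest} × {in TRENI vs not}; OR with +0.5 on all cells when any is
zero, Woolf (log-OR normal) 95% CI, chi-square p without continuity
correction. ORs are suppressed when the family has < 20 TRENI copies
(desk-scale fixtures may lower this floor — that changes only which rows
are reported, not any computed value). The 5′UTR analysis applies the same
machinery to repeats whose placement includes the 5′UTR; all RepeatMasker
families participate, including simple repeats and low complexity.

## Synthetic data

The generators encode the study conditions the analysis assumes: 9
four-cell and 4 eight-cell embryos split 2/2 and 4/4 between lineages;
log2-FPKM = per-gene baseline Uniform(2, 9) + per-(gene, embryo) effect
N(0, 0.5) + ±effect/2 for planted genes (up-lineage drawn per gene and
embryo, as the nested model expects) + cell noise N(0, 0.5), with
FPKM = 2^x − 1 floored at 0. The baseline range keeps the floor from
truncating the noise, so the closed-form Beta null stays exact. Marker
reads are Poisson(50) on the lineage's color (drawn independently per
lineage, reproducing the ~1/4 rate of color-unresolvable embryos) and
zeroed with dropout probability 0.1; mapped pairs are N(21M, 6M).

Imaging counts place each embryo's GFP+/RFP+/unlabeled cells (32–64 total)
across the poles at the rounded expected allocation for a target odds
ratio — OR ≈ 1 for balanced embryos, 5–8 for unbalanced ones (GFP biased
toward the embryonic pole, RFP away, as complementary lineages) — plus ±1
cell of jitter. The rounding choice makes the two regimes cleanly
separable at blastocyst cell counts; real imaging noise (segmentation
error, binomial allocation) is deliberately not modeled, so passing the
classifier tests shows correctness of the decision rule, not robustness to
counting noise.

The annotation generator builds one 3–5-exon reference transcript per gene
(start codon in the second exon in transcript orientation, leaving a clean
annotated 5′UTR), derives novel isoforms by exon skipping (repeat-free) or
by splicing in a repeat-length exon either upstream of the first exon or
into a downstream intron (repeat-bearing, 18% of novel isoforms, 20% of
those in the 5′UTR), draws repeat families from weights skewed toward Alu
while background copies are uniform (so the planted enrichment direction
is real), and emits 20 reads per embedded repeat split between junction
reads (repeat block + nearest-exon block) and repeat-contained reads at a
per-repeat fraction drawn from (0.6, 1.0). One repeat per isoform is
generated; the calling code handles several.

What the generators do not emulate: sequence-level reads, UMI/count noise,
doublets, expression-dependent dropout, overlapping genes, and repeats
spanning exon boundaries partially. Results on synthetic data demonstrate
algorithmic correctness under the stated model, not performance on real
libraries.

## Problem sizes and numerics

Default test/acceptance sizes: 10,000 genes for null calibration, 2,000
genes × 3 seeds for planted-effect recovery, 300–600 reference transcripts
for TRENI recovery — each chosen as the smallest size at which the
corresponding statistical property is sharp. All randomness flows from
`numpy.random.default_rng` seeded per generator stream, so every pipeline
product is bit-identical under a fixed seed. Percentages that mirror
printed summaries are truncated integers; all other reported values are
unrounded floats at the precision shown.
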