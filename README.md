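# rainbowseq

Analysis toolkit for lineage-traced single-cell RNA-seq of cleavage-stage
mouse embryos. In this experimental design each blastomere of a 2-cell
embryo activates one of four heritable fluorescent marker genes
(GFP/CFP/RFP/YFP), founding two traceable division lineages; every cell of
the resulting 4- or 8-cell embryo is then sequenced with a full-length
protocol deep enough to read both the marker and the transcriptome.
`rainbowseq` implements the downstream statistics:

- **Lineage assignment** (`rainbowseq.lineage`): call each cell's expressed
  marker from construct-mapped read counts (winning marker needs ≥10 reads
  and 5× dominance by default), partition each embryo's cells into lineages
  A/B, and apply QC (≥3 million uniquely mapped read pairs; FPKM > 1 defines
  an expressed gene).
- **Blastocyst balance** (`rainbowseq.balance`): from imaging counts of
  marker+/marker− cells in the embryonic vs abembryonic pole, classify each
  embryo as balanced (strictly 1/3 < OR < 3, Haldane–Anscombe corrected) or
  unbalanced, under three counting methods (≥1/3 marker+ inclusion, ≥1/2
  inclusion, or all embryos with the pole-count ratio n1/n2).
- **Variance partitioning** (`rainbowseq.variance`): per gene *g*, a nested
  Gaussian ANOVA with embryo as a factor and lineage nested within embryo
  gives sequential sums of squares SS_embryo, SS_lineage, SS_resid and the
  ratio

      r_g = SS_lineage / (SS_lineage + SS_embryo).

  Under a balanced global null with E embryos, r_g ~ Beta(E/2, (E−1)/2);
  the empirical distribution R of r_g across genes is compared against Beta
  references by KS distance, right-tail probabilities P(R ≥ 1−δ) and Q-Q
  points. Heavy right tails of R indicate a transcriptome-wide lineage
  difference even when no single gene is decisive.
- **Lineage difference tests** (`rainbowseq.difftest`): per-feature nested
  F-test of the lineage term, F = (SS_lineage/d1)/(SS_resid/d_res), BH
  q-values, and a background built by permuting lineage labels within each
  embryo and rerunning the identical pipeline; real vs background q
  ensembles are compared with a two-sample Kolmogorov–Smirnov test and
  counts below q* = 0.01.
- **TRENI calling** (`rainbowseq.treni`): novel isoforms (intron chain
  absent from the reference at the same locus) whose exons overlap a
  RepeatMasker repeat by ≥10 bp are Transposon-Related Novel Isoforms.
  Each embedded repeat is placed relative to the host gene's start codon
  (5′UTR vs downstream, strand-aware) and supported by a junction ratio —
  the fraction of repeat-overlapping reads spliced into the nearest
  annotated exon. Repeat-family enrichment uses per-family 2×2 copy tables
  with odds ratios, Woolf 95% CIs and chi-square p-values (OR suppressed
  below 20 TRENI copies).
- **Synthetic data** (`rainbowseq.simulate`): seeded generators for every
  input — embryos with planted lineage effects and marker dropout, imaging
  counts in balanced/unbalanced regimes, and a toy annotated genome with
  repeat-bearing novel isoforms and junction/contained reads — so the whole
  pipeline runs and is tested without any download.

## Worked example

```sh
rainbowseq run-all --seed 3 --out-dir out/
```

writes TSV tables plus `out/report.md`. With the default configuration
(9 four-cell + 4 eight-cell embryos, 500 genes with 10% planted lineage
effects of 2.0 on the log2 scale, 18 imaged blastocysts, 200 genes' worth
of annotation) the report reads:

```
## lineage assignment
- 68 cells, 0 failed QC, 58 lineage-resolved

## blastocyst balance (per counting method)
   method  n_included  n_unbalanced  percent_unbalanced
one_third          18            12                  66
     half          18            12                  66
      all          18            13                  72

## stage 4cell
- mean expressed genes/cell: 498; union: 500
- 500 genes with defined r; KS vs Beta(1,3)=0.148; KS vs Beta(2,2)=0.479; KS vs Beta(5,5)=0.594
- lineage test: KS=0.540 (p=2.2e-16); q<0.01: real 50, shuffled 0

## TRENIs
- 100 novel isoforms, 18 TRENIs (3 with a 5'UTR repeat)
- 18 embedded repeats, 9 with JR >= 0.9
- TRENI lineage test (4cell): q<0.01: real 1, shuffled 0
```

Reading this: ten cells stay lineage-unresolved (marker dropout plus
embryos whose two lineages drew the same color); two-thirds of imaged
blastocysts are unbalanced under each counting method; the planted lineage
effects drag the real q-value distribution far below the shuffled
background (50 genes at q < 0.01 vs none in the background) while the
balance of SS_lineage against SS_embryo puts R's right tail above every
Beta reference; and all 18 planted repeat-bearing isoforms are recovered,
half of them with junction support at JR ≥ 0.9.

Individual stages are available as `rainbowseq simulate | assign-lineage |
balance | variance | difftest | treni`, each reading/writing plain TSV,
GTF, BED or BAM/SAM.

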