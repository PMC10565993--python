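# Methods

## The uniparental design and what it identifies

Parthenogenetic (PA) embryos develop from activated oocytes and carry two
maternal genomes; control (CN) embryos are biparental. Under this design a
maternally methylated germline imprint behaves predictably: PA methylation
ratio ≈ the maternal allele's level (both alleles maternal), CN ratio ≈ the
average of the maternal and paternal levels. A fully maternal-specific
imprint therefore produces a PA-vs-CN methylation difference of ≈ 0.5 at
the imprinted CpG island, and a maternally silenced gene is expressed in CN
but (almost) not in PA. The package encodes exactly this interpretation:
PA-hypermethylation = maternal methylation; CN-biased expression = paternal
expression. Allelic-expression evidence from heterozygous SNPs corroborates
monoallelic expression but cannot assign its parent of origin without
parental genotypes, so it annotates verdicts and never changes them.

## DMR calling

Candidate regions are contiguous CpG runs inside gap-chained clusters
(inter-CpG distance < 300 bp, i.e. a gap of exactly 300 breaks the chain),
with more than 10 CpGs (≥ 11) and |mean per-CpG group-difference| strictly
greater than 0.2. All three thresholds are read literally as strict
inequalities. The segmenter enumerates qualifying runs by prefix sums
(O(n²) per cluster) and keeps the inclusion-maximal ones — a run contained
in a longer qualifying run is dropped; two overlapping runs neither of
which contains the other are both kept. This enumeration is exact by
construction and is verified against an independent brute-force oracle in
the tests; we chose it over heuristic recursive binary splitting precisely
because exactness is checkable.

The per-region statistic is a two-sided Mann–Whitney U comparing the
vector of per-CpG PA-mean ratios with the per-CpG CN-mean ratios (normal
approximation with tie correction; all-tied input returns p = 1 exactly).
With two biological replicates per group, replicate-level tests have no
power, so CpGs serve as the exchangeable unit. The cost is that spatial
correlation between neighboring CpGs is ignored, making p-values
anti-conservative in absolute terms; they function as a ranking statistic,
controlled genome-wide by Benjamini–Hochberg at q < 0.05 over all tested
regions (not per chromosome). The null simulations in the acceptance
checks confirm that, end to end, signal-free genomes essentially never
yield a DMR.

## Read-level allelic methylation

PMD candidates are gap-chained clusters (same chaining parameters as the
DMR caller, reused because the ratio band alone does not define an
interval) that intersect a supplied CpG-island annotation and whose pooled
mean ratio lies in [0.3, 0.7]. Pooling across samples is the default; a
`samples` argument restricts it. Fixed intervals can be supplied instead
(`--regions`), for regions known a priori.

Fragments are the read unit: paired mates are combined and an overlapping
CpG is counted once (first mate's call wins), matching non-overlapping
extraction upstream. A read qualifies with ≥ 3 CpG calls inside the PMD and
its level is recomputed over in-PMD calls only. Hypomethylated means level
in [0, 0.2] and hypermethylated [0.8, 1.0], both endpoints closed (a read
at exactly 0.2 is hypomethylated). A PMD is analyzed only with more than 30
qualified reads (strictly: ≥ 31) and called allelic when both mode
percentages strictly exceed 30. The report's read × CpG matrix is ordered
by read level then read id, columns in genomic order, ready for lollipop
plotting.

## Expression analysis

TPM is computed per sample as (count/length) normalized to a column sum of
10⁶. Differential expression deliberately avoids external fitting
machinery so results are reproducible from the formulas alone:
median-of-ratios size factors (geometric-mean reference over genes with all
counts positive); a single method-of-moments dispersion — the median over
genes of (var − mean)/mean² on normalized counts, floored at 0.01; and a
two-sided conditional negative-binomial exact test on the group sums of
normalized counts (the distribution of one group's sum given the total,
summing probabilities of splits no more likely than observed). The
conditional exact test is conservative, which the 2000-gene null run
quantifies. Fold changes use normalized group means with a pseudocount of
1, so a gene with zero counts in one group gets a finite log2FC; DEG =
|log2FC| > 1 and q < 0.05.

Allelic expression at a heterozygous SNP: indeterminate below 10 reads;
monoallelic when the major-allele fraction is ≥ 0.9 and a two-sided exact
binomial test against 0.5 rejects at 0.01; biallelic when the minor
fraction is ≥ 0.2; otherwise indeterminate. These numeric defaults are
package choices (the underlying classification concept gives no printed
rule); all are configurable.

## Imprinting integration

The promoter window is strand-aware and exactly 3 kb: [TSS−2000, TSS+1000)
on the + strand, mirrored on the − strand. An overlap of ≥ 1 bp matches a
DMR to a gene; among several, largest overlap wins, then smallest q, then
leftmost. One TSS per gene is required in the annotation; choosing it for
multi-transcript genes is an upstream decision. Verdicts are the strict
conjunctions: maternal-hyper DMR + CN>PA DEG ⇒ paternally expressed
imprinted; paternal-hyper + PA>CN DEG ⇒ maternally expressed imprinted; a
matched DMR with balanced or contradictory expression ⇒ inconsistent; no
matched DMR ⇒ not imprinted.

## The synthetic-data generator

The generator emulates the study conditions, not real genomes. One
chromosome carries non-overlapping genes (alternating strands, 4-kb
bodies), each with a promoter CpG island of 30 CpGs at 50-bp spacing
centered on the TSS, inside the 3-kb window. Imprinted genes (the planted
truth) carry a maternal igDMR over the island — maternal allele methylated
at 0.95, paternal at 0.05 — and are expressed from the paternal allele
only; all other CpGs sit at a 0.05 background. Defaults: 20 genes, 1
imprinted, 2 replicates per group (the embryo study's replicate number),
30× coverage, reads spanning 5 consecutive CpGs, 1% bisulfite call error,
NB dispersion 0.05, base expression 500, and a 2% expression "leak" from
silenced alleles — the paper-scale observation that a silenced gene is
expressed at a very low rather than exactly zero level; the precise leak
level is a free parameter and 0.02 avoids zero-inflation pathologies in
the exact test. SNP read depth scales with allele dose around a mean of
30, enough for determinate allelic calls.

Reads are single-allele (each read draws one of the sample's two parental
genomes uniformly) and span consecutive island CpGs only; there is no
fragment-length or sequence model because downstream analysis consumes
only per-read CpG call vectors. Read starts are uniform over the
n_cpgs + span − 1 possible windows and the read count is Poisson with mean
coverage·(n_cpgs + span − 1)/span, which makes the marginal per-CpG
coverage exactly Poisson(coverage). The count table is the exact
column-sum marginal of the emitted reads — asserted in tests. A `somatic`
sample kind (one methylated maternal + one unmethylated paternal allele at
an igDMR) provides the positive control for the allelic-methylation
classifier. All randomness flows from one seed through per-(kind,
replicate, locus) substreams, so identical seeds give byte-identical
files and partial re-runs are reproducible.

What the simulation does *not* model — and hence what passing tests do not
show about real data: genome-scale CpG density variation and non-island
methylation structure, mapping and conversion biases, copy-number or
aneuploidy effects, correlated dispersion across genes, partial (mosaic)
imprints, and reference bias in allele counting. Results on real data
depend on upstream alignment and extraction quality that is out of scope
here.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; Bismark coverage files are
  1-based inclusive on disk, BED/bedGraph 0-based. Strand merging (pooling
  the two symmetric cytosines of a CpG onto the forward position) is on by
  default and idempotent; duplicate file positions are summed with a
  warning.
- Coverage filter default: every sample ≥ 5 reads per CpG — a common WGBS
  floor that keeps per-CpG ratios stable at the simulated depths.
- Mann–Whitney: all-tied regions return p = 1 exactly; p is clipped to
  (0, 1].
- Exact NB test: total count 0 returns p = 1; computation is in log space;
  symmetric in group order. BH is applied over whatever set of regions or
  genes was tested — callers should not pre-filter by effect size after
  testing.
- Segmentation ties: inclusion-maximality needs no tie-break; the output
  is sorted by (chrom, start, end).
- `classify_allelic` with zero qualified reads reports insufficient_reads
  with both percentages 0.

## Problem sizes in the validation runs

The test suite and acceptance script size their simulations for desk-scale
determinism: 100 random segmentation instances of ≤ 50 CpGs; 200
signal-free genomes of 6 genes for the null DMR rate; a 2000-gene null
differential-expression run; 20 end-to-end simulations at the default
conditions for sensitivity/false positives; 100 somatic simulations for
allelic-region recovery. These sizes give Monte-Carlo standard errors
small enough for the stated bounds while keeping a full run under a minute.

## Known limitations

The per-CpG MWU treats CpGs as independent; its p-values are not
calibrated under spatial correlation (by design, documented above). The
exact NB test with a single common dispersion ignores gene-specific
dispersion. PMD discovery is island-anchored, not genome-wide. The
pipeline assumes single-TSS gene models, assumes upstream deduplication
and M-bias handling for real data, and does not phase reads with SNPs —
read-level bimodality, not haplotype assignment, is the allelic evidence.
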