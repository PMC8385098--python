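# Methods

This note records the model, conventions, defaults, and design choices
behind `scapa`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and the UTR model

All interval I/O follows BED conventions: 0-based, half-open. A PAS is
stored as the 0-based genomic coordinate of the last transcribed base.
Each gene carries one representative 3'-UTR (`UtrModel`): a stop-codon
coordinate, ordered exon blocks, and a spliced length. The `utr_length`
of any genomic position inside the blocks is its 0-based spliced distance
from the stop-codon coordinate, so introns never contribute; a site one
intron-free kilobase past the stop codon has `utr_length` 1000 whether or
not an intron was spliced out in between. A PAS exactly at the stop
codon has spliced distance 0, carries no UTR, and is left unlinked.
"Downstream" is always the 3' direction of the annotated strand.

## Annotation integration

*Within-database collapse* (default radius 10 nt) chains sites in 5'→3'
order: a site joins the open cluster when it lies within the radius of
the cluster's current most-downstream member, and each cluster is
replaced by that member. Chaining by the most-downstream member (rather
than the cluster seed) is a deliberate choice — it makes the operation
order-independent and mirrors the downstream preference of the collapse
rule itself; with radius 10 the positions {0, 8, 16} collapse to {16}.

*Sequential union* starts from the first database in the configured order
and adds from each later database only the sites with no same-strand
neighbour within the radius in the running set. Sites added from the
same database do not block one another (they were already collapsed).
The result satisfies a pairwise guarantee: any two same-strand sites in
the union are more than one radius apart. Database overlap summaries
(`pairwise_overlap`) use an inclusive ±20 nt criterion; "within ± N nt"
is everywhere read inclusively (distance ≤ N).

*UTR integration* keeps, per unique stop codon, the resource entry with
the longest spliced UTR, then extends its terminal block to the farthest
bulk 3'-end-sequencing cleavage position whose spliced distance from the
stop codon stays within 5,400 nt. The cap is applied to the *spliced*
distance — the genomic-versus-spliced question is genuinely open, and
spliced was chosen for consistency with `utr_length` (the extension
region itself is intron-free, so the two differ only through upstream
introns). Per gene, the transcript with the most UTR-mapping reads
represents the gene; ties break by a seeded uniform draw, and genes with
no UTR reads fall back to the longest UTR so every annotated gene stays
linkable.

PASs inside the UTRs of two or more distinct genes are dropped as
gene-ambiguous rather than double-counted; the same rule applies to
reads.

## Read filtering and assignment

The read 3'-end is the 3'-most aligned reference base (soft clips
ignored); reads must be sense-strand with respect to the UTR. BAM input
excludes secondary/supplementary/unmapped alignments; UMI collapsing is
considered upstream, and counts are per read by default.

The acceptance window is −300/+20 nt around a PAS, *in spliced UTR
coordinates*. A genomic window could jump an intron and silently miss
authentic 3'-ends a few bases upstream of a PAS near an exon junction;
the spliced convention makes the window mean the same thing for every
site. Both bounds are inclusive.

Greedy assignment runs in two passes: reads with exactly one candidate
PAS are tallied first; each remaining read goes to its candidate with the
largest unique tally, ties broken by the most downstream candidate
(consistent with the collapse rule's downstream preference, and
deterministic). Because pass-2 decisions depend only on the fixed pass-1
tallies, per-PAS counts are invariant under read order.

QC diagnostics: the read-count funnel (input → UTR-mapped →
PAS-assigned), the strand-aware offset histogram around isolated PASs
(no same-strand neighbour within ±400 nt, 5-nt bins), the mean
downstream A-fraction per read class (20 nt 3' of the read end on the
sense strand), and gene-body counts for the expression-bias contrast.

## Quantification

`IIR(p)` is the fraction of a gene's 3'-end reads whose isoform extends
at least to spliced position `p`; it is 1 up to the first PAS, drops just
*after* each PAS (a read at a site of length L still includes position
L), and its discrete integral over p = 1..max equals the count-weighted
mean isoform length — an identity the tests exercise on random instances.

The gene×cell length matrix stores weighted mean lengths with missing
(not zero) entries where a gene has no reads in a cell; deviation
matrices subtract each gene's mean over nonmissing cells; per-cell scores
average deviations over genes; aggregations by label mask any bin with
fewer than 20 contributing cells (configurable). PAS entropy is Shannon
entropy in bits with 0·log 0 ≡ 0.

MAD between two IIR profiles of the same gene is averaged per nucleotide
over the model's spliced extent (the evaluation grid is genuinely open;
per-nucleotide was chosen because it weights disagreement by the length
of UTR it affects — a per-breakpoint mean is available via direct
evaluation of the profiles).

Expression sums PAS-assigned reads over each gene's unique sites,
normalizes per group to counts per million, and log2-transforms with a
1-cpm pseudocount by default (configurable, 0 allowed) since raw zeros
otherwise have no logarithm; fold changes use the same transform on both
sides.

## Statistics

The χ² statistic is the cellwise Σ(O−E)²/E with E the marginal product;
zero rows/columns are dropped first, and tables left with fewer than two
rows or columns are reported degenerate rather than tested. The default
df is the classical contingency (r−1)(c−1); a `flat_df` mode provides
r·c−1 (a one-sample test on the flattened table with supplied expected
counts). Classical df is the statistically standard choice; the mode
exists for compatibility with the flattened-table reading. Per-PAS tests
use each row's share of the cellwise sum on c−1 df (the row statistics
add up to the gene statistic by construction) and are flagged at
p < 0.05. Gene-level p-values get Benjamini–Hochberg q-values, with m
equal to the number of genes actually tested after the per-group
read-count thresholds (100 per stage, 20 per cluster, configurable).
ANOVA and Wilcoxon helpers apply Bonferroni correction capped at 1; the
Wilcoxon p is exact for small tie-free samples and uses the
tie-corrected normal approximation otherwise. The aggregated-deviation
ANOVA is run on per-cell deviation scores grouped by label (an
interpretation choice; per-bin means are recoverable from the
aggregation API).

The RBP screen keeps RBPs reaching 2 cpm in at least one stage or
cluster sample, computes the stage axis (log2 cpm last minus first
stage) and the neuron axis (mean log2 cpm in neuronal clusters minus
others), tests each RBP's stage counts against the pooled counts of all
other RBPs by χ² (Bonferroni over tested RBPs), compares neuronal vs
other clusters by Wilcoxon, and reports the Pearson and Spearman
correlation between the two axes.

## Synthetic data

The generator emulates the statistical structure the pipeline is built
for: genes with 1–2 introns inside the UTR; 2–4 PASs per gene spaced
350 nt (spliced) so acceptance windows are disjoint and planted
proportions are identifiable (spacing is configurable down to the 20-nt
invariant for ambiguity testing); three databases derived from the truth
with ±3 nt jitter and 10% dropout; five stages × four clusters of
labeled cells; true read offsets from a truncated geometric with mode
−10 nt upstream (10% uniform over (−10, +20]), reflecting the empirical
concentration of poly(A)-primed 3'-ends just upstream of the cleavage
site, with a uniform alternative; and internal-priming reads terminating
immediately 5' of A-tracts (15 nt, minimum 6) planted in introns —
outside every PAS window by construction. The genome background is
i.i.d. uniform ACGT so the downstream A-richness contrast between
artifact and authentic reads is unambiguous. Half of all reads are
artifacts by default: real nucleus-derived libraries lose up to an order
of magnitude of reads to non-3'-end positions, but most of that loss is
deep-intronic; among UTR-proximal candidates an even split is a
realistic middle ground.

Planted effects: a global stage-wise lengthening of 75 nt per stage step
in expected mean 3'-UTR length (implemented by mixing proximal- and
distal-leaning usage vectors per gene), a 10% subset of strongly
differential genes with an additional 0.3 proximal→distal proportion
shift ramped across stages, and a 20% subset of "induced" genes whose
expression rises across stages and in neuronal clusters (for the RBP
screen). Every read records its origin (true PAS or artifact locus), and
all randomness descends from a single seed through named substreams, so
the same configuration reproduces outputs byte for byte.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: sequencing errors, barcode
collisions and UMI duplication; non-uniform genomic base composition
(real introns are A-richer, so real artifact filtering leans harder on
the annotation than on sequence contrast); PAS microheterogeneity beyond
database jitter; ambient RNA; and genes overlapping on the same strand
(overlap is only generated on request to exercise the ambiguity rule).

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small
instances chosen to make every check sharp: oracle comparisons use 1,000
random collapse/union instances and 300 greedy instances with ≤5 PASs
and ≤50 reads; χ² and BH implementations are compared with quadratic
references to 1e-9 on tables up to 20×10 and p-vectors up to 10,000;
calibration uses 5,000 genes × 5 groups at depth 500 over 10 seeds;
parameter recovery uses 200 cells per stage and depth 10,000 with 99%
binomial intervals scored across all gene×PAS marginals. Entropy uses
0·log 0 ≡ 0; BH q-values are order-preserving and capped at 1;
identical-sample Wilcoxon comparisons short-circuit to p = 1.

## Known limitations

Gene linkage relies entirely on the representative-UTR annotation: PASs
(and reads) in unannotated UTR extensions are lost unless bulk 3'-end
evidence extends the model. Reads are counted, not UMI-collapsed, by
default. The per-PAS χ² decomposition treats rows independently though
they share the column margins, as is conventional. The MAD grid and the
5,400-nt cap conventions are package choices where the underlying
definitions are open (see above). No figure rendering is provided —
matrices and tables only.
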