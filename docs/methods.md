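# Methods

This note documents the statistics `mlseq` implements, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and known limitations.

## Data model

The unit of analysis is the *redundant* read set: all sequenced read
instances of one library, aggregated per unique sequence (`ReadSet`).
`R` is the total instance count, `NR` the number of distinct sequences, and
the complexity `C = NR/R` lies in `[1/R, 1]` — near 0 when all reads are
identical, 1 when all differ.  Reads are placed on the genome by exact,
full-length, gap-free matching of the read or its reverse complement
(equivalent to a brute-force scan of every substring of the read length; the
implementation uses a k-mer index).  Reads containing ambiguity codes never
match, by construction of the no-mismatch criterion.  SAM input is accepted
as an alternative; only records with CIGAR `<k>M` and `NM == 0` are kept so
that ingested alignments satisfy the same criterion.

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on load.  Gene expression is the algebraic sum of the counts of
the unique reads incident with the gene.  A read whose placements hit more
than one gene contributes its full count to each (annotation classes are not
mutually exclusive either); such reads are identifiable via
`multi_gene_reads` and can be excluded.  Coverage vectors `y[i]` (the summed
abundance of reads overlapping position `i`) are computed on the unspliced
genomic gene span by default — the simplest testable convention — with an
exon-concatenated option.

## Quality control

* **Strand bias** on CDS-incident redundant reads: `|P − 0.5| + |N − 0.5|`,
  where `P` and `N` are the proportions of plus- and minus-strand
  placements.  Since `P + N = 1` this equals `2|P − 0.5|`; both forms are
  tested for agreement.
* **Per-gene complexity difference**: for two replicates, `|C_A − C_B|` per
  gene, binned by log2 mean incident abundance (width-1 bins, lower-edge
  inclusive — the bin width is a choice; plots in this field show binned
  axes without stating one).  Reference lines at 0.05 and 0.1.  A
  *hump* — three or more consecutive bins with median `|ΔC|` above 0.05 — is
  the signature of a replicate with distorted duplicate structure.
* **Jaccard top-N similarity** (default N = 1000): `|top(A) ∩ top(B)| /
  |top(A) ∪ top(B)|`.  Ties at rank N are all included, making the set
  deterministic and order-independent (the set may exceed N).
* **Correlation matrices**: Pearson, Spearman, Kendall (tau-b, the
  tie-corrected variant) on gene-expression vectors.
* **p2pPCC**: the Pearson correlation between two samples' coverage vectors
  of the same gene.  Undefined (NA) when either vector is constant —
  including all-zero coverage — and excluded from bin medians.  Invariant
  under positive affine scaling of either vector.
* **Offset estimation**: the smallest abundance-bin lower edge such that for
  *every* replicate pair the median p2pPCC of that bin and all higher bins
  exceeds the threshold (default 0.7; 0.5 is also defensible and the
  threshold is exposed as a parameter).  The worst-pair rule is the most
  conservative reading of "for all replicates"; pooling pairs is the
  alternative.  Returned on the linear abundance scale (2^bin-edge), so
  estimates land on powers of two; NA when no bin qualifies, in which case
  the pipeline falls back to 20 with a warning.
* **Outlier flagging**: a replicate is flagged when (a) its complexity
  profile against *every* sibling shows a hump, and (b) its similarity to
  its siblings is lower than a reference similarity.  For (b) the reference
  is the remaining siblings' similarity to each other when the condition has
  ≥3 replicates, else the replicate's similarity to other-condition samples;
  both the Jaccard matrix and a pairwise median-p2pPCC matrix can serve as
  the similarity source.  The p2pPCC source matters: a perturbation of read
  *placement* leaves abundances — and hence Jaccard — untouched while being
  equally visible against every sample, so only the sibling-to-sibling
  baseline discriminates the odd replicate.  Equidistant replicates are
  never flagged.  Exclusion is never silent: the pipeline drops flagged
  replicates only with `auto_exclude`.

## Normalization

Subsampling operates on the redundant read set *before* expression
summarization, with ncRNA-incident reads (t/rRNA-like contaminants) removed
first.

* **Without replacement** (the primary scheme): drawing a fixed total such
  that each read instance can be chosen at most once makes the unique-read
  counts exactly multivariate hypergeometric.  The implementation delegates
  to `numpy.random.Generator.multivariate_hypergeometric` (marginals
  method), which is exact and linear in NR.  Subsampled counts can never
  exceed the originals; per-read variance carries the finite-population
  correction and is strictly below the with-replacement variance.
* **With replacement** (comparison baseline): multinomial with fixed
  probabilities `c_i/R`; may over-amplify abundant reads and drop rare ones.
* **Incremental consistency check**: subsample at 95%, 90%, …, 45% (11
  fractions; the main protocol range — a wider 99–40% variant is available
  through the `fractions` parameter) and verify that (i) the redundant
  genome-matching proportion stays within ±0.5 percentage points of the
  original (the tolerance is a choice, configurable) and (ii) the mean
  per-gene p2pPCC between subsample and original stays above 0.95.
  Alignments are re-used rather than re-mapped: a without-replacement
  subsample is a subset of the original unique reads, so its placements are
  already known.
* **Fixed-total subsampling with bootstrap**: the target defaults to the
  minimum depth of the accepted samples.  `n_boot` (default 10) independent
  subsamples are drawn; each is judged by its gene-level expression PCC to
  the original (all must exceed 0.95), and one is then selected at random,
  its seed recorded.  Targets below 55% of a library's depth are computed
  but flagged `requires_review` for case-by-case assessment.
* **Quantile normalization**: every column is mapped onto the mean of the
  sorted columns; ties receive rank-averaged reference values.  This
  matches `limma::normalizeQuantiles` exactly (verified against it on a
  tied matrix) and is exactly idempotent on tie-free data; with ties the
  reference implementation drifts identically on re-application.  The
  pipeline applies the correction only when column distributions actually
  differ (max pairwise Kolmogorov–Smirnov distance > 0.01).
* **RPM scaling**: abundance × (mean depth / sample depth).

## Hierarchical differential expression

With two or three replicates, variance estimates per gene are unstable, so
the evidence per class is the **maximal CI** `[min, max]` of the replicate
normalized expressions — a conservative envelope (a single replicate gives a
degenerate interval and the result is marked low-confidence).  DE between
two classes requires strictly disjoint intervals; the amplitude is
`|OFC|` between the proximal ends, and the call threshold is 1.5-fold,
applied as `≥ log2(1.5) ≈ 0.585` (the non-strict reading of "more than
1.5-fold"; the boundary case is a measure-zero event on real data).
Touching intervals (`hi_lower == lo_higher`) are not DE — their proximal
fold is exactly 1.  Overlapping intervals get amplitude 0 by convention.
Consequences verified by tests: every called gene has non-overlapping
replicate ranges, and the call set shrinks monotonically as the offset
grows.

The two-step hierarchical call for a two-level design: (i) per gene, sum
expression over the lower-level classes within each top-level class and
categorize the gene by the top classes expressing it — "expressed" meaning
summed abundance above the offset, treating the offset as the noise floor
(the categorization cut-off is otherwise undefined); (ii) within each top
class of the gene's category, test the lower-level classes on maximal CIs.
A gene categorized into one body part only is never tested — hence never
called — in the other, which is what removes leaky genes from the foreign
treatment comparison.  Genes categorized "both" are tested independently in
each body part.  Level ordering is data-driven: descending median per-gene
`|OFC|` between class means, ties broken by IQR then declared order, with an
overlap diagnostic (fraction of between-class amplitudes below the 95th
percentile of replicate-pair amplitudes) that quantifies how subtle a level's
effect is.  Direction is reported from class means, robust to a single
extreme replicate.

CV diagnostics use the sample standard deviation (ddof = 1) over replicate
groups, with reference lines at 0.25 and 0.5; MA tables report per-gene
(log2 mean abundance, OFC) with reference lines at 0 and ±0.5.

## Synthetic data generator

`synth_data` emulates the structure of a nested behavioural-transcriptomics
experiment at desk scale: a random genome with non-overlapping gene models
(UTRs, optional introns, interspersed ncRNA loci), a 2 body parts × 2
treatments × 3 replicates design, log-normal per-gene base abundances
(median 200 units, σ_ln = 0.8), 40% body-part-specific genes of which a
quarter leak at 1% into the foreign part, shared genes carrying log-normal
body-part effects (σ = 1.5 log2 — between tissues most genes differ, which
is what makes the body-part level dominate the ordering), a 20% subset with
a ±1 log2 treatment effect, multiplicative log-normal replicate noise
(σ = 0.05), and per-sample depth jitter.  The outlier mechanism re-draws a
fraction (default 0.5) of one replicate's reads at a few anchor positions
per gene, raising the duplicate rate (lowering per-gene complexity) without
changing totals — reproducing the complexity-hump phenomenology and the
contrast between the two subsampling schemes: the hump survives
without-replacement subsampling and is attenuated (directionally, over
seeds) by with-replacement subsampling.

Two entry points: `simulate_reads` (full read-level studies written as
FASTA/GFF3/FASTQ; multinomial allocation of reads to loci, uniform start
positions, configurable strand balance) and `simulate_counts` (matrix-level
expression with direct control of the replicate CV, for DE studies where
read placement is irrelevant).  Everything is reproducible byte-for-byte
from the seed.

What the generator does **not** emulate: sequencing errors and quality
scores, GC/positional bias, spliced reads (reads are drawn from the
unspliced span, so intron coverage is realistic for pre-mRNA only),
paired-end layouts, and genome-scale gene counts.  Passing tests therefore
demonstrate correctness of the statistics and the qualitative phenomena they
detect, not performance on error-laden full-scale libraries.

## Problem sizes and numerical notes

Simulated studies use 20–80 genes and 6k–120k reads per library — chosen so
the full suite and the acceptance script run in seconds while keeping
per-gene read counts in the regimes each analysis needs.  Two regimes
matter and pull in opposite directions on short genes:

* the complexity-based outlier analysis needs *unsaturated* duplicate
  structure (reads per gene below the number of distinct placements);
  at saturating depth all libraries look equally duplicated and the hump
  vanishes — true of real data too, where it would require far deeper
  sequencing relative to transcriptome size;
* the incremental consistency criterion (mean p2pPCC > 0.95 down to 45%)
  presumes deep per-gene coverage; shallow desk-scale libraries legitimately
  fail it, so the consistency demonstrations use a deeper single library.

Other numerical choices: abundance bins are `floor(log2(abundance))`;
binomial/hypergeometric simulation checks use 3-standard-error bands
(~1000 draws); bootstrap and subsample seeds are drawn from a master
generator (below 2^31) and recorded in outputs; the exact-match index is
rebuilt per genome (no on-disk index).

## Known limitations

* Exact full-length matching is deliberate (it is what the QC statistics
  assume) but discards reads with any mismatch; real applications may prefer
  ingesting pre-computed exact alignments via SAM.
* The maximal-CI rule's stringency grows with replicate number (wider
  envelopes, fewer calls); it is designed for 2–3 replicates.
* Level ordering by median |OFC| can be indecisive when fewer than half the
  genes respond to a level; the overlap diagnostic and IQR are reported so
  the user can inspect borderline orderings.
* `estimate_offset` quantizes to powers of two (bin edges); a finer offset
  requires narrower bins.
* The intersection matrix and class proportions use redundant counts and
  non-exclusive class membership; they are descriptive, not a partition.
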