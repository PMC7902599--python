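# Methods

This document states exactly what `pollenx` computes: the model behind each
stage, the operational thresholds, what the synthetic generator does and
does not cover, the numerical choices, and the limitations.

## Coordinate and overlap conventions

All internal coordinates are 0-based half-open; GTF/GFF3's 1-based
inclusive convention is converted at I/O time only. "Overlap" always means
at least one shared base. Transcript–transcript overlap is exon-level;
overlap against reference genes treats the gene as its whole body.
Distance between non-overlapping intervals is the number of bases strictly
between them; overlap gives distance 0; intervals on different chromosomes
have no distance.

## Locus grouping

Transcripts form a locus (XLOC) iff they are connected by a chain of
pairwise exonic overlaps on one chromosome. Strand restricts overlap only
where both strands are known: models with strand "." (non-strand-specific
assembly) join either strand. Identifiers are assigned in order of
leftmost coordinate (`XLOC_%06d`), so numbering is a deterministic function
of the input set. The implementation is a union-find over a start-sorted
sweep; an independent connected-components oracle verifies it in the test
suite.

## Novelty

A locus with any exonic overlap against a gene of the older reference
annotation is *known* and excluded from the cohort. Otherwise, overlap
with the newer annotation makes it *recent* (annotated between the two
reference generations), with neither *novel*. Transposable-element
features never confer known/recent status.

## Biotype

Applied to the longest (spliced length) transcript of a locus:

1. spliced length < 200 nt → **short** (exactly 200 nt falls through);
2. else longest ORF ≥ 100 codons → **orf_coding**;
3. else **lncRNA**, refined to **lincRNA** iff the locus span is ≥ 500 bp
   from the nearest protein-coding gene body and no exon overlaps a
   transposable element.

ORFs are bounded ATG..stop spans; the peptide length counts the initiator
Met and excludes the stop. Codons containing N never match the start or a
stop. Known-strand transcripts are scanned on their sense strand only;
unknown-strand ones on both strands of the spliced sequence. Open-ended
ORFs (no in-frame stop) are not reported. A brute-force oracle confirms
the scanner on random sequences.

## Expression

Two normalizations, used for different purposes:

- **RPM** = count / library size × 1e6, with the library size taken from
  the sample sheet (total sequenced reads), not the column sum of assigned
  reads. Threshold calls use condition-mean RPM per dataset: PEX > 1,
  hPEX > 10, present ≥ 0.05, each satisfied by the best condition of the
  dataset. PSX = PEX in at least one pollen dataset and < 1 RPM in every
  condition of every sporophytic dataset.
- **Median-of-ratios size factors** (the DESeq definition: per-sample
  median of count/geometric-row-mean over loci positive in all samples)
  normalize the counts for the differential test.

### Differential expression

Per dataset, heat stress vs control, after a low-count filter (keep a
locus if any sample has ≥ 10 reads):

- dispersion: per-locus method-of-moments estimate
  `(var − mean) / mean²` averaged across conditions, then **pooled** as
  the median over loci and shared by all loci (floor 1e-8). Pooling is the
  decisive numerical choice: a 3-replicate moment estimate is far too
  noisy to standardize a Wald statistic, and the pooled estimator is
  correct when dispersion is shared across loci (as in the generator
  model). Measured on 2000-locus calibrations: null type-I error ≈ 0.08 at
  nominal 0.05, power ≈ 1.0 for a 4-fold change at base mean 100. The
  per-locus estimator remains available (`pool_dispersion=False`).
- LFC = log2 of normalized condition means with pseudo-count 0.5; SE by
  the delta method under the NB mean-variance relation
  `var = m + α m²`; two-sided p from the normal reference; BH adjustment
  over the loci tested in that dataset. Loci with all-zero counts in both
  conditions are flagged `undefined` and excluded from adjustment.
- DEX iff |LFC| ≥ 1 and adjusted p < 0.05.

No fold-change shrinkage, outlier refitting, or independent filtering is
performed; the test implements the study's decision rule, not a general
replacement for DESeq-class software.

## Phylostratigraphy

Lineages are flat root-to-tip node lists compared positionally from the
root. For each homology hit with E ≤ 1e-5 (self-species hits excluded),
the lowest common ancestor with the focal lineage is found; the locus
stratum is the root-most of those LCAs. Loci without passing hits belong
to the focal-species stratum. The lineage file is treated as
authoritative; an unknown hit taxon is an error, not a silent skip.

## Protein-homology bins

blastx-style tabular hits are filtered at E ≤ 1e-7; the best remaining hit
per locus (lowest E, then highest identity) is binned by percent identity:
none < 50, partial [50, 97), full ≥ 97. Loci without passing hits are
"none".

## miRNA target scoring

The expectation of an antiparallel miRNA:site duplex is the sum of
per-position penalties — 0 for Watson–Crick, 0.5 for G:U, 1.0 for
mismatch, 2.0 for a bulged (unpaired) base — doubled at miRNA positions
2–13 counted from the 5' end. Sites are reported at expectation ≤ 3.0. At
most one bulge (on either strand, never terminal on the miRNA) is
considered. The best site per (miRNA, locus) is chosen by lowest
expectation, then 5'-most position, then ungapped register. Mode is
*cleavage* iff positions 9–11 are all Watson–Crick, else *translational
inhibition*. The scan is vectorized (penalty matrix plus prefix/suffix
cumulative sums over bulge registers); exhaustive enumeration verifies it
on random instances, including sites flush with the sequence ends.
miRNAs shorter than 15 nt are rejected.

## Ribosome profiling

A P-site track holds per-nucleotide P-site counts on a transcript
(P-site = read 5' end + a length-specific offset). A periodic-footprint
(PF) P-site is a position with count ≥ 1 — raw-count thresholding in place
of signal denoising; the decision rule consumes only per-frame PF position
counts and the threshold is configurable. A transcript is *considered*
at ≥ 1 RPM footprint coverage in at least one condition; frame tallies are
taken on the condition-summed track; *translated* requires the best frame
to hold ≥ 5 PF positions, and ≥ 2 such frames flag *multi-frame*. An
exact two-sided binomial test of the best frame against 1/3 accompanies
each call.

## Synthetic data generator

`pollenx.simulate` produces a full input set (genome FASTA, two reference
annotations, TE annotation, transcript GTF, count matrix and sample sheet,
P-site tracks, homology and lineage tables, miRNA FASTA) plus a
ground-truth JSON. Design:

- One `numpy` generator seeded from the config; stages draw in a fixed
  order, so outputs are byte-reproducible for a given config.
- Defaults are the study conditions: 312 loci, ~79 % recent, class mix of
  1 % short / 78 % lncRNA / 12 % lincRNA / 9 % ORF-containing, three
  pollen datasets plus one leaf dataset, 3 replicates, 2M-read libraries,
  NB dispersion 0.05.
- Features are placed sequentially with explicit gaps, so distance
  constraints (lincRNA ≥ 500 bp; planted violations at 80–350 bp) hold by
  construction. Noncoding loci are sanitized by injecting stop codons on
  both strands until no ≥ 100-codon ORF remains, with planted miRNA sites
  protected by genomic position.
- Planted mean-RPM levels ({4, 30, 100} base, ×4 or ÷4 fold changes on the
  two upper levels, leaf {0, 8, 30}) keep every threshold call several
  standard deviations away from its cutoff at the default library size and
  dispersion, so threshold truth equals the call on sampled counts with
  overwhelming probability.
- P-site tracks place in-frame signal at planted ORF codon starts and thin
  off-frame noise on the condition-pooled track below the PF threshold, so
  planted translation status is recovered exactly.

**Scope:** the generator covers intergenic loci on a uniform random
genome. It does not model GC or repeat structure, splice-site sequence,
multi-mapping reads, batch effects, varying per-locus dispersion, or
partially overlapping gene structures; those are outside the study model
the package implements.

## Numerical choices

- Dispersion pooling and the normal Wald reference (see above) — the
  calibration trade-off is documented with measured type-I/power values.
- Pseudo-count 0.5 on normalized condition means keeps LFC finite when one
  condition is zero.
- Exact binomial (not chi-square) for frame periodicity: PF position
  counts are small.
- The miRNA scan enumerates bulge registers with cumulative-sum algebra
  rather than alignment DP; with ≤ 1 bulge the two are equivalent and the
  former is O(m·L) with vectorized inner loops.
- BH adjustment runs within each dataset, matching the per-dataset testing
  design.

## Limitations

- The NB Wald test assumes a shared dispersion across loci when pooling;
  with strongly locus-dependent dispersion the per-locus mode should be
  used and its calibration re-checked.
- Recovery guarantees of the generator are probabilistic margins, not
  certainties; DEX agreement in particular is bounded by the test's power
  and type-I error, not by construction (measured ≈ 99.9 % at defaults).
- `recount_from_supplementary` recomputes headline counts from a per-locus
  characterization table with a declared column schema; it applies this
  package's rules and cannot reproduce numbers that depended on steps
  outside those rules.
- Phylostratum assignment is only as good as the lineage table and hit
  list; detectability bias (short/young proteins are harder to hit) is not
  corrected.
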