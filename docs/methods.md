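# Methods

This note documents the models, parameter choices and numerical details of
the package, and what the synthetic benchmark does and does not establish
about real data.

## Scope and design stance

The package re-implements, as library code, the genome-recovery and
community-profiling analysis applied to deep HiFi sequencing of a
microbial community: assembly-graph topology triage, genome quality
ranking, MinHash/ANI dereplication, catalog novelty assessment,
depth-based composition, and direct (amplification-free) full-length 16S
profiling from reads. Heavy external components that the original
workflow delegates to dedicated tools — the assembler itself, binning,
lineage-aware marker HMM scoring, plasmid/virus HMM classification,
reference taxonomy databases, tree building — are out of scope; where the
pipeline needs their *outputs*, it either consumes a drop-in table (e.g. a
precomputed completeness/contamination table) or uses a small, declared
surrogate suitable for synthetic data (see below). Each surrogate is its
own method with its own tests; none claims to reproduce the external
tool's output bit-for-bit.

## Synthetic communities (`synthio`)

The generator is the benchmark's source of ground truth, so its defaults
encode the study conditions rather than being free knobs:

* **Community**: 12 taxa (10 bacteria, 2 archaea), log-normal abundance
  weights (σ = 1.5) with the dominant taxon forced to ≥ 60% — the strongly
  skewed, single-taxon-dominated profile characteristic of a food-waste
  digester (~70% of cells in one lineage). Two plasmids and one virus ride
  along at 5% of their host's weight; chromosomes are 1.0–1.3 Mb circular
  replicons (the generator enforces the 1 Mb chromosome/mobile-element
  size split that the completeness analysis relies on).
* **Planted features**: each chromosome carries 1–5 complete rRNA operons
  (16S–23S–5S contiguous on one strand, ~4.7 kb, well inside the 10 kb
  colocation window), one gene per listed tRNA isotype, and one verbatim
  copy of each of 40 synthetic universal single-copy markers. Operon and
  copy-number truth feed the 16S copy-number correction.
* **Reads**: lognormal lengths with σ = 0.55 and μ set from the target
  N50 via the base-weighted-median identity N50 = exp(μ + σ²) (default
  target 14,254 bp; empirical N50 lands within ~5%). Per-read base quality
  is an integer drawn from a 5-wide window whose centre is calibrated by
  bisection so that the full quality distribution (window plus ±2 per-base
  jitter) has mean error probability exactly 1 − mean_accuracy (default
  0.9994). Substitutions are then drawn per base at the Phred-implied
  probability, which makes quality strings unbiased accuracy estimates *by
  construction* and keeps the Phred ↔ identity mapping exact for the
  filter tests. Errors are substitution-only (HiFi indel rates are low and
  indels would break that exactness); an indel fraction parameter exists
  but is reserved. Circular replicons produce origin-spanning reads;
  coordinates are 0-based half-open and wrap at the replicon length.
* **Graphs**: circular replicons become self-linked segments with a
  duplicated-head overlap recorded in the link CIGAR; strain tangles are
  built by cutting 1%-diverged variants at shared boundaries and
  cross-linking every junction; junk linear contigs are added so all three
  topologies occur. By default the lowest-abundance chromosome is
  presented as a tangle — deliberately unrecoverable by circular-contig
  extraction, which reproduces the qualitative observation that read-level
  16S profiling sees taxa that assembly misses.
* **Reference sequences**: the 16S/23S/5S templates, marker panel and
  tRNA genes are synthetic stand-ins generated from fixed internal seeds.
  The 16S scaffold (1,542 bp) has ten conserved 25 bp blocks at roughly
  the canonical conserved-region positions; genera differ only in the
  variable regions (~8% per-genus substitution). They mimic the
  conserved/variable *architecture* of the real molecules, not their
  composition.

## Stage-by-stage notes

**Graph triage.** Components are connected components of the undirected
link multigraph, so reversing any link record leaves membership unchanged.
A single segment is circular only with a (s,+,s,+) or (s,−,s,−)
self-link; the palindromic (s,+,s,−) form does not join head to tail and
forces `tangled_circular`. Multi-segment components are all labelled
`tangled_circular` (tangles include non-cyclic "other complex
structures"); a `has_cycle` flag (edges ≥ nodes) is recorded for
transparency. Overlap trimming accepts only exact match CIGARs ("100M");
anything else raises rather than guessing.

**Genome quality.** The completeness/contamination surrogate weights all
markers uniformly and ignores collocation sets — a declared divergence
from lineage-aware marker scoring; on real data one should supply an
external tool's table (the pipeline accepts that as a drop-in). The
built-in detector is exact substring counting of the packaged synthetic
markers, valid because the generator plants them verbatim. The operon
counter requires the 23S and 5S to start within 10 kb downstream of a
same-strand 16S; 10 kb and the 16S→23S→5S order are configurable since
colocation distances are convention, not a published constant.

**Dereplication.** Sketches use splitmix64 over 2-bit-packed canonical
k-mers (k = 21, s = 1000); the Jaccard estimate is computed within the
merged bottom-s sketch, d = −(1/k)·ln(2j/(1+j)), capped at 1 for j = 0.
Fragment ANI cuts the query into consecutive 1,020 bp fragments
(trailing partial fragment dropped from the denominator), anchors each by
k-mer seeds every 10 bp on both strands (diagonal voting in 200 bp bins,
leftmost diagonal on ties, ≥ 3 votes required, ≤ 8 positions per
repetitive seed), and aligns it with edlib to a window of ± 20% of the
fragment length around the anchor. Fragments with identity ≥ 30% are
retained; ANI is the mean retained identity, coverage the retained
fraction; the pair's ANI is the mean of the two directional runs and both
coverages are kept because the species rule needs both. The seed
requirement is what keeps unrelated genomes at coverage ≈ 0 (random
21-mer collisions are negligible). Representative selection is greedy by
descending Cp − 5·Ct (ties: higher Cp, then lexicographic id, logged);
the original "many runs of comparison and selection" order is unspecified,
so borderline chains may split differently — a declared choice.

**Novelty.** 16S identity uses a semi-global edlib alignment (end gaps
free on the longer sequence) with identity = matches / alignment columns
spanning the shorter sequence; whether the original identities came from
local or global alignment is not stated, so the semi-global choice is
declared, not inferred. With multiple 16S copies the maximum identity is
used — conservative against false novelty. Bands: < 95% novel genus,
[95, 97) novel species, ≥ 97% known; genomes without a 16S stay
unassessed. Catalog matching prefilters at Mash d ≤ 0.1 before fragment
ANI.

**Abundance.** Read assignment uses (w = 11, k = 17) minimizers: most
shared minimizers wins, an absolute floor of 10 shared minimizers stands
in for the mapped-read identity filter of depth summarisation tools, ties
break lexicographically and are logged. The covered interval is the
min/max of matched minimizer positions after restricting to the largest
position run with gaps below 1.5× the read length — without that
localisation, reads overlapping repeated elements (identical operon
copies) would claim intervals spanning distant loci; spans are further
clamped to the read length so assigned bases can never exceed read bases.
Depth, not base fraction, is the abundance weight (base fraction is
emitted as a secondary column); edge effects at contig ends are ignored.

**16S profiling.** Detection is conserved-anchor co-occurrence: 15-mers
from the conserved blocks (plus every 1-mismatch neighbour) are matched
on both strands; hits are grouped by diagonal (read position minus
reference offset, tolerance 20% of the gene length — a diagonal-cluster
approximation of per-gap spacing checks), and a group with ≥ 3 distinct
anchors becomes a candidate whose boundaries are the outermost anchors
extended to the reference ends. This surrogate replaces covariance-model
search and is only claimed valid where the anchors are guaranteed present
(i.e. on synthetic data); candidates truncated by read edges are flagged
and removed by the length filter. The classifier is the canonical
naive-Bayes bootstrap scheme: per-genus 8-mer presence probabilities with
(count + 0.5)/(n + 1) smoothing (the simple one-level form), genus
assigned by full-word-set likelihood, confidence as the fraction of 100
bootstrap trials — each scoring a random 1/8 subsample of the gene's
words — agreeing at each rank, and calls below confidence 0.8 rolled up.
The 1/8 fraction and 0.8 cutoff follow the canonical description since
the source protocol states neither. Copy-number adjustment divides taxon
counts by the table's copies at the lowest classified rank with an entry,
falling back to ancestors and then to a default of 2.0; mean base error
is computed on the probability scale (mean of 10^(−Q/10)), not mean Q.

## Benchmark sizes and statistics

The acceptance benchmark uses problem sizes chosen to make the measured
quantities statistically stable on a single CPU: 1 Mb genome pairs for
ANI recovery; 10 species × 3 variants of 200 kb for dereplication; 50
pairs of 10 kb sequences for the MinHash-vs-exhaustive comparison; ≥ 50
labelled graph components for triage; and five seeded end-to-end runs of
the default community at mean per-replicon depth 6× (~80 Mb of reads and
~150–250 full-length 16S genes per seed). Community-recovery error is
assessed on the profile averaged over the five seeds (per-taxon absolute
error ≤ 3 percentage points) with the Pearson correlation pooled across
seeds — the averaged form is used because a single seed's 16S profile
rests on a few hundred genes and its dominant-taxon error is
binomially ~1.5–2 pp wide.

## What passing tests do and do not show

The generator's reads have uniform-ish per-read quality, no indels, no
chimeras or adapters, and position-independent errors; its 16S genes all
share one scaffold length and guaranteed conserved anchors; its taxa are
~10% diverged with clean strain structure. Passing the suite therefore
shows the *algorithms* are implemented correctly and recover planted
truth under HiFi-like error rates — it does not show that the anchor
detector matches covariance-model sensitivity on real rRNA, that the
marker surrogate matches lineage-aware completeness, or that minimizer
assignment matches a real mapper on closely related strains. Those
stages are exactly the ones designed to accept external tools' tables as
drop-ins.

## Known limitations

* Tangled components are triaged but not re-assembled (external).
* The ANI seed-and-extend is tuned for ≥ ~90% identity pairs; distant
  homology is reported as undefined rather than estimated.
* Classifier confidence is not calibrated against a real reference
  database; copy numbers for unlisted taxa default to 2.0.
* Strain mixtures below the species threshold are collapsed by
  dereplication by design; sub-species resolution is out of scope.
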