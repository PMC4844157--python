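# Methods

`famscan` implements the computational core of a genome-wide gene-family
survey in an allohexaploid plant genome, of the kind used to characterize
lectin receptor kinases (LRKs) in bread wheat: domain-composition
classification, homolog clustering and nomenclature, duplication calling,
cross-species orthology, distance phylogenetics and RPKM expression
profiling.  This note records the models, parameter choices and numerical
conventions, and what the synthetic validation genome does and does not
establish about real data.

## Family definition and domain models

A gene is an LRK when its protein carries a Ser/Thr protein-kinase domain
together with at least one extracellular lectin domain; the lectin type
fixes the class (legume-type → L-LRK, bulb/GNA-type → B-LRK,
calcium-dependent → C-LRK).  Accessory S-locus glycoprotein and PAN/APPLE
domains, common in B-LRKs, are retained as evidence but never change the
class.  When two lectin types co-occur with a kinase (observed in no real
family list we are aware of, but possible in principle) the higher-scoring
lectin decides and the gene is flagged ambiguous.

Domain detection uses packaged position-specific scoring matrices rather
than profile HMMs.  Each packaged model is a consensus-anchored PSSM
(consensus residue +5, others −2) with a hit threshold of 60% of the
consensus self-score, which admits members diverged up to roughly 30% from
the consensus while rejecting shuffled sequence (the empirical null in the
test suite scores 100 shuffles of a real family protein and finds no
hits).  These scaled-down models (36–70 columns) are adequate for
synthetic and consensus-like sequences; for real proteomes the intended
path is a pre-computed domain-hit table (five-column TSV, convertible from
`hmmscan` output) which bypasses the scanner while keeping the
classification rule.

Molecular weight uses average residue masses plus one water (Biopython's
ProtParam).  The isoelectric point is found by bisection on the
Henderson–Hasselbalch net-charge curve with an EMBOSS-style pKa table
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1) to 0.01 pH; tests verify the charge at the returned pI is ~0 and
cross-check against Biopython's independent implementation.

## Alignment layer

All similarity searches run through an affine-gap Gotoh aligner (local and
global) with BLOSUM62 and the BLAST protein defaults, gap open −11 /
extend −1, where the opening position carries the open penalty.  Traceback
ties break diagonal > up > left, so results are deterministic.
`identity_pct` counts identical columns over all alignment columns
including gaps (BLAST `pident` convention); the survey's "identity" and
"similarity" thresholds are both interpreted as this quantity over the
local alignment.  Significance is gated by the Karlin–Altschul expectation
E = K·m·n·e^(−λS) with the gapped BLOSUM62 parameters λ = 0.267,
K = 0.041, at the survey's threshold of 1e−10.

Correctness is established two ways: (i) scores equal an exhaustive
enumeration over all alignments, implemented independently of dynamic
programming as enumeration of monotone column matchings with optimally
packed gap runs (valid whenever |open| ≥ |extend|); (ii) scores match
Biopython's `PairwiseAligner` under the same scheme.

A shared-k-mer prefilter (k = 5, ≥ 25 shared distinct k-mers) keeps
all-vs-all searches desk-scale.  Pairs at or above the 80% duplication
gate share hundreds of 5-mers, so the filter is conservatively permissive;
the suite verifies both the superset property (every gate-passing pair
survives) and that clustering output is identical with the filter on or
off.

## Homology layer

Homolog clusters are single-linkage connected components over pairs with
identity strictly above 90% at E ≤ 1e−10.  Single linkage is deliberate:
in a hexaploid the A/B/D homoeologous copies of one gene may be mutually
~87–95% identical while each exceeds 90% to the ancestral-most copy, and
single linkage groups them the way unigene-anchored clustering does
(complete linkage is available by flag).  Nomenclature numbers clusters by
descending size then representative id; the longest member (ties: smallest
id) is the "gene" (`L-LRK13`), the rest are its homologs (`L-LRK13.2`),
ranked by length.  Naming is invariant to input order.

Duplication events are same-pseudo-molecule pairs at ≥ 80% identity
(E-gated): tandem within 5 Mb of start-to-start distance, segmental
beyond.  Pairs with a scaffold-located member are real events whose
category cannot be determined (chromosomal position unknown) and are
reported uncategorized.  Pairs on different chromosomes (homoeologs) are
never duplication events.  Orthologs are best bidirectional hits: (x, y)
is reported iff each is the other's unique top-scoring cross-species hit,
ranked by alignment score (mirroring bit-score ranking), then identity,
then id.

## Phylogenetics

Full-length proteins are aligned by deterministic center-star
construction: the center maximizes the summed global-alignment score to
all others; other sequences merge under "once a gap, always a gap";
columns that are gaps in more than half the rows are then removed (the
"aligned fragments" extraction).  Center-star trades some alignment
fidelity against progressive aligners for exact reproducibility; at the
≥ 90% within-family identities it is applied to here the difference is
immaterial.  Distances are p-distances with pairwise deletion of gap
positions (pairs sharing no gap-free column get distance 1).

Neighbor joining follows Saitou–Nei with the standard two-point
branch-length formulas; Q-matrix ties break to the lowest index pair and
negative branch lengths are clamped to zero with a flag on the tree.  The
headline property — NJ returns the generating topology on additive
distances — is exercised on 100 random 8-leaf trees.  Bootstrap supports
resample alignment columns with replacement, rebuild the tree per
replicate, and report the percentage of replicates containing each
internal bipartition of the original tree; one RNG stream (a single
integer seed) drives the whole run.  The default is 1000 replicates (the
conventional choice for this kind of survey); validation uses 100 for
speed, which is ample to separate ~100% supports from noise.

## Expression

"100% query coverage and sequence similarity" mapping is implemented
literally: a read counts toward a gene iff it occurs verbatim as a
substring of the transcript or its reverse complement, via an exact k-mer
index at read length.  Reads matching k > 1 genes contribute 1/k each by
default (`all` and `discard` modes available).  RPKM = count·10⁹ /
(transcript length · library total); the library total is whole-library
metadata from the sample sheet, not the family-mapped count, because the
per-million denominator refers to the sequencing library (a family-mapped
fallback is used when the metadata is absent).  Fold changes average
replicate RPKMs per side and compute FC = (mean_t + c)/(mean_c + c) with
pseudocount c = 0.1 RPKM so responses from near-zero baselines stay
finite; a gene is affected at FC ≥ 2 (up) or ≤ 0.5 (down).  Statistical
testing beyond the fold rule is out of scope.  Specificity summaries
report the top-10 genes per sample (ties by id) and each gene's
highest-mean organ.

## The synthetic study

The generator emits the structure the pipeline consumes in a real survey:
wheat-style gene-model identifiers encoding sub-genome/chromosome/arm,
A/B/D homoeolog triplets at 93–98% identity, duplicate copies at 82–95%
identity placed within 5 Mb (tandem), beyond it (segmental) or on
scaffolds, a sister species with one ortholog per family at ~85%
identity plus one non-reciprocal decoy, kinase-only/lectin-only/random
negative controls, and 52 condition-structured samples (5 organs × 3
stages × 2 replicates, plus two biotic contrasts at 24 h and
heat/drought/combined contrasts at 1 h and 6 h against mocks).

Choices that make the planted truth exact rather than approximate:

* Mutations are substitutions with exact counts (no indels), so realized
  identities are deterministic; every within-family pairwise identity is
  additionally checked against guard margins around the 80% and 90% gates
  (the 82–95% duplicate band is sampled excluding ±2.5 points around 90),
  with deterministic resampling on violation.  Family ancestral domain
  blocks are diverged ~18% from the model consensus so cross-family local
  alignments stay far below the 80% gate.
* Back-translation jitters deterministically between the two most
  frequent codons per residue, keyed by a mixed hash of (gene id,
  position).  A plain CRC proved unusable here — CRC32 is linear over
  GF(2), so same-length ids produced perfectly correlated codon choices —
  hence the splitmix64 finalizer.  With the mixer, no two transcripts
  share a read-length k-mer, multi-mapping vanishes, and mapped counts
  equal planted counts exactly.
* Read counts are independent Poisson draws per gene (no multinomial
  coupling), so a strong responder does not compositionally depress its
  neighbours' fold changes.  Planted responders sit clearly off the 2×
  boundary (5×, 3×, 0.33×, 0.2×, one ~49× biotic responder) with boosted
  baselines, so sampling noise cannot flip a label at the default depth
  (20 000 expected reads/sample over 178 genes).

What passing does not show: tolerance to sequencing error, indel
polymorphism, alternative splicing, positional read bias or overdispersed
counts — none of which the generator models — nor scanner sensitivity on
real Pfam-scale domains.  The pipeline's logic (gates, rules, bookkeeping,
determinism) is what the synthetic study validates.

## Degenerate inputs and numerical conventions

Coordinates are 1-based inclusive throughout.  Local alignments with no
positive-scoring region return score 0 and an empty trace.  Proteins
shorter than a domain model simply cannot hit it.  Empty clusters never
arise (singletons are clusters of one).  p-distance of a pair with no
co-ungapped column is 1.  `fold_changes` requires non-empty contrast
sides; `rpkm` rejects non-positive denominators.  All stage outputs are
sorted and written with fixed float formatting, so re-running any stage
with the same config and seed reproduces files byte-for-byte.

## Problem sizes used in validation

The default study is 50 families (16 L / 32 B / 2 C), 178 gene models in
the focal species, 51 in the sister species, 16 duplication events and 52
read sets — large enough that every rule fires on many instances while a
full pipeline run stays around a minute.  Bootstrap validation uses 100
replicates on 18-taxon sub-alignments; tree-stage defaults remain 1000
replicates.
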