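# Methods

`haplosv` calls and genotypes structural variants (SVs, events ≥ 50 bp)
from mapped high-accuracy long reads by modeling each variant's *local
haplotype*: the assembled alternate-allele sequence together with its
flanking anchors. Discovery runs per sample; merging and genotyping run
jointly across samples, comparing haplotypes as sequences rather than as
per-caller variant representations. This note describes the model,
the tunable parameters, the synthetic data the tests run on, and the
numerical choices and limitations a user should know about.

## Pipeline model

1. **Signatures.** Each primary/supplementary alignment is scanned for
   SV-associated evidence: indel CIGAR runs ≥ `min_signature_size`
   (default 35 bp — deliberately below the 50 bp SV definition so that
   events fragmented by the aligner still seed a candidate; the final
   |SVLEN| ≥ 50 filter is applied after refinement), split-read junctions
   between consecutive query segments of one read (with breakend
   orientations derived from strand and segment order), and terminal
   soft-clips ≥ `min_clip_size` (200 bp). Same-kind indel runs on one
   read separated by ≤ `max_gap` (50 bp) merge.
2. **Clustering.** Single-linkage over a pairwise link relation: indels
   link when same kind, within `max_dist` (500 bp) and with size ratio ≥
   `size_ratio` (0.5); split junctions link when both breakends agree in
   position (≤ `max_dist`) and orientation. Soft-clips never seed a
   cluster (weak evidence) but may attach to one. Clusters need
   `min_cluster_support` (2) distinct reads. Single-linkage can chain
   nearby events; assembly separates alleles downstream, so over-merging
   is recoverable.
3. **Assembly.** Supporting reads' query subsequences over the cluster
   span padded by `flank` (500 bp) are extracted orientation-normalized
   (split reads are projected through their forward segments), grouped by
   complete-linkage on edit-distance/mean-length with `split_threshold`
   0.05 into at most `max_haplotypes` (2, diploid) groups, and each group
   is collapsed to a consensus: the medoid segment is the backbone and
   every other segment votes per backbone column (substitutions,
   deletions, and inserted strings each by majority). The consensus
   engine is a contract, not an implementation: any engine that returns
   the input when inputs agree, removes singleton errors by majority, and
   respects the haplotype cap is acceptable; the tests check exactly
   those properties.
4. **Refinement.** Each consensus haplotype is globally aligned to its
   anchor window with affine-gap scoring match 1 / mismatch −5 / gap open
   −6 / gap extend −0.5. Mismatch is priced an order of magnitude above
   gap extension so that one large event — including the scrambled
   diagonal an inversion would otherwise produce — aligns as a single
   deletion run plus a single insertion run, and chance matches shorter
   than ~12 bp cannot split a run. Haplotypes whose anchor flanks align
   below 90% identity are dropped. Indel runs ≥ 50 bp become
   sequence-resolved DEL/INS records; a paired D/I run whose inserted
   sequence reverse-complement-matches the deleted segment, or a cluster
   whose split junctions carry inverted orientations, becomes an
   inversion, reported as two component breakends plus a summarizing INV
   event. Insertions whose sequence matches the reference immediately at
   the insertion point (located by infix alignment, identity ≥
   `dup_min_identity` 0.9) are reclassified as tandem duplications;
   dispersed copies stay INS. Cross-contig split clusters become BND
   records directly, with the fused allele sequence constructed from the
   two reference sides.
5. **Breakpoint normalization.** All junctions are left-normalized.
   Deletions carry microhomology (HOMLEN/HOMSEQ): the size of the
   interval of breakpoint placements that produce an identical alternate
   sequence, computed by flank extension and verified in tests against
   an exhaustive placement-enumeration oracle. Insertions are rotated to
   their leftmost placement; because a long tandem copy can slide far,
   the normalization re-runs over a window wide enough to hold the whole
   slide. Inversions use a dedicated canonical form — the minimal
   (leftmost, then shortest-compatible) equivalent placement — because
   chance matches at inversion edges create ambiguity even between
   placements of different width. Junction-inserted sequence and
   microhomology are mutually exclusive annotations at one junction;
   mixed cases resolve in favor of homology.
6. **Merging.** Haplotypes from all samples whose anchors overlap within
   `max_merge_dist` (500 bp) are compared over the common reference
   window; edit-distance/mean-length ≤ 1 − `merge_similarity` (0.98)
   means same allele. Allele indices are assigned by descending total
   support with a lexicographic sequence tie-break, so numbering is
   reproducible. One sample contributes at most two alleles per locus.
7. **Genotyping.** Every read over the locus is assigned to the allele it
   supports. Two scoring modes:
   * *Whole window* (window and every allele sequence ≤ 5 kb): the read
     subsequence spanning the window is globally aligned against the
     reference window and each allele sequence; assignment needs a
     `min_score_margin` (10) edit-distance margin.
   * *Junction probes* (larger events, and bare breakends): ~1 kb probes
     centred on each novel adjacency of each allele (deletion junction,
     insertion ends, the copy1-end/copy2-start junction of a tandem
     duplication, the two strand-switch junctions of an inversion) are
     matched as infixes of the read on both strands. A probe hit
     (distance ≤ 100 over 1 kb, far above the ~1% error floor and far
     below the ~50% mismatch of a non-carrier) assigns the read to that
     allele even when reference probes also match — a tandem duplication
     destroys no reference adjacency, so carrier reads legitimately match
     both. A reference vote additionally requires the read's aligned span
     to cover a junction interval; a read starting inside the second copy
     of a duplication matches reference probes but is genuinely
     uninformative and stays unassigned. This mode exists because
     whole-window scoring of large events is read-length limited: with
     15 kb reads, an 8-12 kb deletion window starves the reference allele
     of spanning reads and biases het calls toward hom.

   Per-allele counts feed a binomial-mixture likelihood: a read supports
   allele *a* under genotype (x, y) with probability 0.5·f(a|x) +
   0.5·f(a|y), f(a|c) = 1 − ε if a = c else ε, ε = 0.05. With a uniform
   prior over diploid genotypes, GQ = floor(−10·log10(1 − posterior)),
   capped at 999. Worked values: 10 ref / 0 alt → 0/0 at GQ 27; 6 ref /
   6 alt → 0/1 at GQ 40.
8. **Phasing.** Two heterozygous loci in one sample whose allele-assigned
   read sets overlap are phased cis or trans by majority of shared reads;
   blocks take the leftmost locus position as phase set (PS). Conflicting
   evidence leaves the pair unphased.
9. **Depth refinement.** DEL/DUP candidates ≥ `min_depth_event_size`
   (5 kb) are checked against a binned depth track (`bin_size` 1 kb,
   raw depth, no GC or mappability correction): expected ratio 1 −
   0.5·dosage for deletions, 1 + 0.5·dosage for duplications, accepted
   within `depth_tol` (0.25). A candidate matching the opposite class's
   expectation (and failing its own) is reclassified. Depth never
   rescues candidates without breakpoint support; it only annotates or
   reclassifies.

## VCF output

One row per alternate allele (plus breakend rows). DEL/INS below
`symbolic_threshold` (10 kb) are sequence-resolved with a left anchor
base; larger deletions and all DUP/INV are symbolic with END. Inversions
appear both as a symbolic INV row and as their four breakend rows (two
component breakpoints) sharing an EVENT id; breakend mates are reciprocal
and carry MATEID. HOMLEN/HOMSEQ are emitted when homology is present.
At a multi-allelic locus a sample chromosome carrying a *different*
alternate allele is projected to 0 on that row (allele-centric records);
`read_vcf` is the matching lossy inverse for evaluation and concordance,
and retains raw lines so filtered subsets rewrite byte-identically.
Internal coordinates are 0-based half-open everywhere; conversion to
1-based happens only here.

## Synthetic data

The generator builds i.i.d. uniform DNA, optionally overwriting a
fraction of small DEL/INS sites with tandem arrays (unit 2-8 bp) so that
microhomology is exercised; plants non-overlapping events ≥ 50 bp with
≥ 2 kb spacing and chosen genotypes on one or both haplotypes; and
samples reads of length ~N(15 kb, 3 kb) truncated to [1 kb, 30 kb] to a
target depth, with 1% errors (70% substitutions, 30% indels of 1-3 bp).
Alignments are constructed analytically by lifting each read through the
known haplotype-to-reference block structure — CIGARs, split segments and
SA tags are exact by construction, so the whole pipeline is tested
hermetically without an external mapper. Pedigree mode draws founder
haplotypes independently (carrier probability 0.4) and transmits one
haplotype per parent per child by a seeded coin flip, recording the
inheritance vector. Translocations are modeled as terminal inter-contig
fusions (a haplotype leaves the host contig at the junction), so each
carries exactly one junction.

What the generator does *not* emulate: homopolymer-biased HiFi error
profiles, mappability artifacts, segmental duplications or other
genome-scale repeat structure, mosaicism, or reference bias from a real
aligner. Passing tests therefore demonstrate the correctness of the
algorithms under idealized mapping, not end-to-end accuracy on real
sequencing data.

Default study conditions used by the acceptance checks: a 1 Mb contig,
20 events spanning the 50-499 / 500-4999 / ≥ 5000 bp strata across
DEL/INS/DUP/INV, 15% of small events in repeats, 30-fold coverage (with
a 15-fold arm for the titration property), seed 0. One full run takes
well under a minute on one CPU; problem sizes were chosen so the entire
suite runs on a laptop.

A placement detail: planted events keep an `edge_margin` distance from
contig ends (default 3 kb). On short test contigs the margin should be
raised above the read length, because coverage ramps over one read
length at each contig end — a finite-contig artifact that real
chromosomes, and the 1 Mb default, do not exhibit; the depth-ratio
trials use a 30 kb margin for this reason.

## Pedigree concordance

A locus is concordant when some assignment of each parent's two alleles
to haplotypes, with a transmission choice per child, reproduces every
child's genotype. Without an inheritance map this is Mendelian
satisfiability, decided exhaustively (verified against an independent
brute-force enumeration for ≤ 5 children). With a map, transmissions are
fixed per region and only the four parental phasings are searched — the
same phasing must explain all children jointly. Alleles are opaque
labels, so multi-allelic loci work unchanged. The evaluator only scores
genotypes; it never edits them.

## Known limitations and numerical notes

* **Depth-ratio dispersion.** With reads of HiFi length at 30-fold
  coverage, the event-mean depth of a ~10 kb event averages over only
  ~25-30 independent reads, so the inside/flank ratio carries an
  irreducible standard deviation near 0.1 (confirmed against an
  independent marked-Poisson coverage model). A ±0.1 band around the het
  expectation of 0.5 therefore captures only ~70% of events at this
  scale; the refinement tolerance (0.25) is sized for this noise, and
  the ratio concentrates as events grow.
* Ties everywhere resolve deterministically: consensus backbone by
  lowest index among medoids, allele numbering by support then sequence,
  gap placement by left-normalization, GQ by flooring. Reruns with the
  same inputs and configuration are byte-identical.
* Duplication detection is limited to tandem (adjacent) copies;
  dispersed duplications remain insertions. Nested or complex multi-SV
  graphs beyond inversion pairing are out of scope, as are allosome
  ploidy handling (concordance excludes allosomes by default) and
  GC-corrected depth.
* Discovery uses a MAPQ ≥ 10 floor to keep noisy mappings out of
  clustering; genotyping-time scoring re-reads all local reads at
  MAPQ ≥ 0 so every read can vote.
* An insertion of whole units into a tandem repeat array is reported as
  a tandem duplication of those units — the two descriptions are the
  same allele; evaluation treats {INS, DUP} as one insertion class when
  matching calls to planted events.
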