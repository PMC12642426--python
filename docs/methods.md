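# Methods

This note documents the models, conventions and numerical choices behind
`arraykit`, in the spirit of a package methods appendix: what is simulated,
what is estimated, which knobs matter, and what passing tests do and do not
demonstrate.

## att-site recombination model

An att site is `left_arm + core + right_arm`; all four kinds of a family
share the crossover core (default families use a 2-bp core). Recombination
is modelled purely at the sequence level as the unidirectional arm swap

    attL = B_left + core + P_right
    attR = P_left + core + B_right

`integrate(host, array, ...)` requires exactly one attB in the host — zero
hits raise an error, mirroring the real failure mode of an attB landing
site mutated by long-term integrase exposure — and at least one attP on the
(circular) array. The array string is opened at the chosen attP and spliced
in; the product length equals `len(host) + len(array)` exactly and contains
exactly one attL and one attR. Site matching allows substitutions only
(default 0): att sites are short, and indel tolerance invites spurious
hits. Coordinates are 0-based half-open throughout; minus-strand hits are
reported in forward coordinates. No canonical PhiC31 site sequences are
hard-coded; the shipped defaults (`simulate.default_att_sites`) are
arbitrary fixed synthetic sequences with realistic arm lengths (34-bp attB,
39-bp attP), and real experiments should supply their own definitions via
the YAML config (`attsites.load_att_config`). Excision and inter-homolog
recombination are out of scope; the reaction is strictly unidirectional.

## Generative model of array assembly

The simulator emulates arrays formed from injected linear DNA:

* **Composition.** Class counts for one array are multinomial in the mix
  weights. The default mix — 827 fragments at weights
  558 stuffer : 238 selection : 31 transgene — reproduces the fragment
  counts observed in a sequenced ~6.8 Mb integrated array.
* **Stuffer lengths.** Truncated log-normal, µ = 5.5, σ = 1.0, bounds
  40 bp – 100 kb. This puts 91.7 % of fragment lengths under 1 kb
  (matching the ≈ 91.5 % sub-kilobase fraction reported for sheared carrier
  gDNA in assembled arrays) with a tail into the tens of kb. Note that
  published per-array base fractions cannot be reproduced simultaneously
  with the published fragment counts under any single length distribution —
  the megabase totals of real arrays arise substantially from large
  duplications multiplying fragment occurrences — so the generator fixes
  counts and the sub-kb fraction, and leaves base totals to emerge.
* **Ordering.** The order is built sequentially from the remaining
  multiset: the next class is drawn with weight `remaining[c] · w_c` where
  the clustering weight `w_c ≥ 1` applies only when `c` repeats the
  previous fragment's class. `w = 1` for every class reduces exactly to a
  uniform shuffle of the multiset — i.e. the null hypothesis of the
  adjacency permutation test — which is why this one-parameter Markov
  preference was chosen over other exchangeability-violating models.
  Orientation per fragment is uniform. Transgene/selection fragments are
  full length by default; a configurable `truncation_prob` incorporates an
  end-anchored partial copy instead (uniform 30–95 % of the reference).
* **Stuffer genome.** A seeded random 1 Mb pseudo-genome by default, so
  tests need no downloads; any real genome FASTA may be substituted. A
  random genome lacks real repeat families (rDNA-like tandem arrays,
  transposons), so the annotation-exactness results below say nothing about
  repeat-induced ambiguity in real donors.

### Junction micro-homology and canonical boundaries

When the base that would extend a fragment leftward within its source
happens to equal the last placed base of its left neighbour (probability
1/4 per base at a random junction), the fragment boundary is not
identifiable from the sequence: several boundary placements yield the
identical array. Both the simulator's emitted truth and the annotator
therefore **left-align** every boundary within its micro-homology run —
the same canonicalisation VCF applies to indels. The emitted sequence is
unchanged; truth and annotation become comparable fragment for fragment.

### Duplications

Each event copies a contiguous run of whole fragments (total length drawn
from the configured range, default ≥ 50 kb) and inserts the copy at a
fragment boundary, consistent with repeats in real assemblies being
composed of multiple DNA fragments. Events are sampled mutually
non-overlapping (disjoint origins; no insertion strictly inside an origin)
so each origin/copy pair stays an exact repeat in the final coordinates —
one consistent realisation of a process whose timing (during vs after
assembly) real data cannot distinguish. A planted pair flanked on both
sides by identical sequence (e.g. the same selection-marker fragment
preceding both origin and copy) is only identifiable together with that
flank; recovery is therefore scored against the pair's maximal exact
extension, computed independently of the detector.

### Reads

Paired-end FR reads with normal insert sizes (default 150 bp reads,
400 ± 40 bp inserts), uniform start positions, optional uniform
substitution errors. With `error_rate = 0` both mates are exact
(reverse-complemented) substrings — the regime the internal mapper is
guaranteed for. All stages derive their RNG streams from one seed via a
`SeedSequence` keyed by a stage-name hash (`arraykit._seeds`), so every
stage is independently reproducible bit for bit.

## Fragment annotation

Contigs are segmented right to left: at the current segment end the
terminal `min_anchor`-mer (default 25 bp, packed 2-bit) is looked up in a
sorted k-mer index over both strands of every reference, each placement is
extended leftward to its maximal exact match, and the longest extension
wins (ties by leftmost source coordinate, then strand). This yields
exactly the left-aligned canonical segmentation, so on error-free input
annotation equals simulator truth; fragments shorter than `min_anchor`
(the smallest fragment reported in real arrays is 43 bp) are left in the
unannotated fraction. The matcher is substitution-free by design — the
package's synthetic inputs are error-free — and real, noisy contigs should
be aligned externally and ingested via `annotations_from_paf` (alignments
with indels are squared up by end-trimming to the substitution-only
interval model).

Composition statistics: class base fractions over total contig length
(annotated + unannotated sums to 1 within 1e-9); per-source full-length
counts, where *full length* means source coverage ≥ 0.98 of the reference
(a convention — the underlying notion is not numerically defined in the
field) and applies only to transgene/selection classes; stuffer coverage
as the union of source intervals over the donor length; and the per-base
copy-number spectrum, counting every annotation including those inside
duplications, with uncovered donor bases contributing multiplicity 0 to
the below-k fraction (default k = 5).

The expected below-k fraction under pure random shearing has a closed
form: per-base multiplicity is Binomial(n, E[L/(G−L+1)]) (equal-p
Poisson-binomial; edge effects of order E[L]/G ignored), implemented in
`simulate.expected_fraction_below` and used as the independent check on the
spectrum.

## Repeat detection

Contigs are compared all-vs-all and against themselves (off-diagonal) by
shared 21-mers occurring ≤ 20 times (masking scattered transgene copies,
as an aligner's repeat filter would), chained on a common diagonal with
gaps ≤ 10 kb, then extended outward to maximal exact matches — extension
restores full event boundaries across any masked interior. Matching is
forward-strand only: duplications formed by re-ligation of array segments
are direct repeats, and inverted-repeat detection is out of scope. Because
no external aligner runs, there is no MAPQ; each hit instead carries a
uniqueness score on the familiar 0–60 scale: 60 with a unique equally good
partner, else `-10·log10(1 − 1/m)` for `m` tying partners (≈ 3 for a
two-way tie), with partners found through per-contig interval trees
(length within 5 %, ≥ 90 % overlap). The published filter is applied with
strict inequalities — length > 50 kb **and** quality > 50 — matching its
wording; the equivalence between this internal score and an aligner's MAPQ
is approximate and intentionally not asserted. External alignments with a
real quality column can be substituted via `hits_from_paf`.

## Clustering permutation test

Statistic S = number of adjacent same-class pairs of the focal class,
summed over contigs, plus the wrap pair on circular sequences. (An
alternative — the number of focal fragments with ≥ 1 same-class neighbour
— is available behind `statistic="fragments"`; the pair count is the
default.) The null shuffles all labels jointly across contigs and refills
the original slot sizes: with contigs arising from one circular molecule
split only by assembly limits, the global permutation is the
least-assumption null. The estimator is add-one, (b+1)/(n_perm+1) with
b = #{S* ≥ S}, never zero, rendered `< 1/(n_perm+1)` when b = 0; the
default n_perm = 1e5 is the minimum consistent with reporting p < 1e-5.
Because S is discrete the add-one p is uniform only up to its lattice;
calibration checks therefore use the uniformized p
`(b_strict + U·(ties+1))/(n_perm+1)`, which is exactly U(0,1) under the
null. The null distribution depends only on the label multiset and slot
sizes — not the observed order — so replicate studies at one composition
may compute it once (`permutation_null`) and score many observed values
against it. An exhaustive oracle enumerates all distinct multiset
orderings for ≤ 10 fragments. No multiple-testing correction is applied
across the 2–3 classes; raw p-values are reported.

## Insertion-site calling

Reads are mapped against a combined reference (host chromosomes + payload
sequences from the injection mix). Evidence: (a) split reads — primary +
supplementary alignments of one mate on host and payload with a soft clip
≥ 20 bp on the junction-facing host side; (b) discordant pairs — mates on
host and payload (skipped for pairs already contributing split evidence;
disable with split-only mode to use split reads alone). Evidence positions
are clustered per host chromosome **and junction side** by single linkage
within 500 bp, dropping clusters under 3 reads — so one integration yields
two calls, the attL-side and attR-side flanks, at (nearly) the same host
locus, as breakend sides are reported for structural variants. The 500 bp
window and 3-read floor are conventions standing in for the manual
inspection a human would do in a genome browser.

`naive_map` is a unique-exact-k-mer-anchored mapper (k = 21): a read maps
where its first/last k-mer anchors extend; junction reads get primary +
supplementary records with complementary soft clips; ambiguous anchors
leave the read unmapped, never misplaced. A short middle stretch matching
neither side (≤ 50 bp, e.g. a residual att arm at a junction) is
tolerated. It is guaranteed only for error-free reads and exists to make
the simulated pipeline self-contained; real data should be aligned with a
production aligner and fed in as SAM. SAM I/O goes through pysam with
standard 1-based on-disk coordinates.

## Problem sizes used in tests and the acceptance script

All sizes are package choices balancing statistical resolution against a
desk-scale run: annotation exactness at N = 500–827 fragments on a 1 Mb
donor; calibration with 200 null replicates (n_perm = 2000 for the KS
uniformity check, 1e5 for significance floors) at the 827-fragment
composition; repeat recovery with 21 planted 50–65 kb events in a ~4 Mb
array (N = 3000); insertion calling over 100 seeded replicates of a ~85 kb
integrated molecule at 30× (20 replicates in the acceptance script), plus
no-integration controls; copy-number spectrum from 5000 fragments on 1 Mb
(per-base sampling intensity ≈ 2, the regime where ~95 % of donor bases
occur fewer than five times).

## Known limitations

* The annotator and mapper assume substitution-free sequence; noisy
  long-read contigs require external alignment.
* Repeat detection is forward-strand and exact; diverged or inverted
  repeats need an external aligner (PAF ingestion is provided).
* The random pseudo-donor lacks real repeat structure; results on real
  genomes with multi-copy loci will include genuine multi-mapping
  ambiguity the synthetic tests cannot exhibit.
* Rolling-circle tandem structure of plasmid-derived arrays is not
  modelled; the assembly model covers linear-injection arrays.
* The uniqueness score approximates, but is not, an aligner MAPQ.
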