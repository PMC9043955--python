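# Methods

## The locus model

A 5S rDNA locus is modeled as a head-to-tail array of repeat units between
two single-copy flanks. Each unit is a conserved CDS (default 120 bp,
GC 0.55) followed by an intergenic spacer (IGS; default 210 bp, GC 0.50 —
the typical spacer is 190–220 bp). A *ribotype* is a distinct IGS sequence;
any difference, one substitution or an indel, separates two ribotypes. A
repeat whose CDS carries an indel or ≥3 substitutions relative to the
intact-unit consensus is treated as a pseudogene (the threshold
operationalizes "several" substitutions, given that an intact copy normally
carries at most two; both the indel rule and the threshold are
configurable).

## Synthetic data generator (`simarray`)

The generator *defines the study conditions* for every test:

* Ribotype `R1` is the ancestor; each further ribotype differs by
  `snps_per_ribotype` substitutions (default 4 — chosen to match typical
  reported intragenomic spacer similarities of ~96–99 % over ~210 bp, i.e.
  several differences per pair), optionally one indel from `indel_spec`,
  and, for the last ribotype, an internal tandem duplication. A minimum
  pairwise edit distance can be enforced (the exact-recovery conditions use
  2); collisions are re-drawn up to 20 times, then fail.
* Planted duplication divergence (`copy_snps`, `copy_indel_bp`) is placed so
  the truth stays identifiable: copy substitutions are isolated (pairwise
  ≥10 bp), ≥15 bp from the copy boundaries and ≥10 bp from the copy indel.
  A substitution sitting on a copy boundary or abutting the indel makes the
  planted anatomy itself alignment-ambiguous (split indels, shifted
  boundaries), i.e. not a detector failure but an unidentifiable truth.
* Copy counts follow the mixture proportions by largest-remainder rounding
  (a proportion rounding to zero copies is an error); the copy order is a
  seeded shuffle; a configurable fraction of copies is pseudogenized by one
  random 1–2-bp CDS indel or three CDS substitutions.
* Libraries are uniform, strand-symmetric reads with i.i.d. substitution
  errors and constant base quality; single-end count =
  round(coverage × array length / read length). Default 1×250 bp at 100×:
  phasing near-identical spacers through the conserved CDS requires reads
  that span adjacent variant sites, and 250-bp single-end (MiSeq-style)
  reads cover a 190–220 bp spacer between CDS anchors. A
  `background_read_fraction` of reads is drawn from a seeded non-rDNA
  sequence as a filter-specificity control.
* Sequences are drawn with *exact* (rounded) GC composition, so the GC
  parameter is meaningful at spacer length.

Not emulated: quality decay and indel-type sequencing errors, PCR
duplicates, GC-coverage bias, multiple loci, and recombination between
ribotypes. Passing tests therefore demonstrate correctness of the
algorithms under clean library statistics, not robustness to every real
Illumina artifact.

## Read filtering (`cdsfilter`)

All overlapping 20-mers of the CDS and their reverse complements are used
as exact probes; a read (or pair, if either mate hits) is kept iff one of
its windows equals a probe. Exact matching mirrors the usual SRA-side
pre-filter; errors inside a window lose that window only, and since probes
tile the full CDS the filter stays sensitive for reads overlapping the CDS
by more than the probe length. Filtering is idempotent and strand-
symmetric.

## Assembly and unit recovery (`unitasm`)

k-mer counting is strand-canonical (lexicographic minimum of k-mer and
reverse complement; k odd so no k-mer is self-complementary), k = 31.
Nodes below `min_kmer_coverage` are pruned; maximal unbranched paths are
compacted into unitigs; pure cycles are linearized at the lexicographically
minimal rotation over both strands and flagged circular.

Coverage threshold: at real sequencing depths a threshold of ~100 reads
removes single-copy genomic background. For the synthetic conditions used
here (100× depth, 20-copy array), error-free runs use 5, error-bearing runs
use 20: with substitution errors at 0.002 a recurrent same-site error k-mer
over a 12-copy ribotype reaches coverage ~5 (Poisson mean ≈ 1), while the
weakest true signal (a 2-copy ribotype) sits near 175 — 20 separates the
two by orders of magnitude on both sides.

CDS anchoring locates full or terminal-fragment CDS occurrences on a
contig: exact 20-mer seeds vote for candidate offsets, each candidate is
verified by infix alignment (edlib) with up to 5 edits, so pseudogenized
copies with small CDS indels still anchor. Units are cut between
consecutive co-oriented anchors (`extract_repeat_units`); contigs with CDS
hits on both strands are flagged anomalous and skipped.

Because coexisting ribotypes share the CDS and most of the spacer, their
variants form bubble chains and no unitig contains a complete spacer.
`assemble_units` therefore threads every read through the unitig graph and
enumerates cyclic CDS-to-CDS paths under a read-support discipline:

* every junction crossed must be traversed by at least one read;
* whenever the graph offers a choice, the chosen unitig must co-occur in
  reads with **every** earlier branch choice a read could physically span,
  **at the spacing the path implies** (gap recorded per read; tolerance
  3 bp). Gap-consistency is what distinguishes within-unit phasing evidence
  from reads that merely cross the junction into a neighbouring repeat copy
  of a different ribotype, where the same two alleles co-occur at a
  different spacing.
* support is two-tier: pairs a read spans with ≥50 bp to spare need 8
  gap-consistent reads (a single error read can fake an entire short allele
  span by converting a variant site into the other allele, giving 1–4 false
  supporters; genuine phasing at such gaps has dozens at any usable depth),
  while pairs near the physical span limit need only 2.
* the DFS root counts as a phased choice (a root sitting on an
  allele-bearing CDS fragment must not escape its own phase checks), paths
  are capped (500 paths, 3000 bases, ≤2 visits per unitig to allow
  duplication loops), and stitched paths are cut by the CDS-anchor
  extractor and deduplicated by sequence.

Output is deterministic (sorted traversals everywhere) and invariant under
reverse-complementing every input read.

## Ribotype calling (`ribotypes`)

The CDS consensus is the column-majority over intact units (two passes: a
provisional consensus over all units selects the intact set, then the
consensus is recomputed; ties alphabetical). Integrity is judged on a
global affine alignment (match +1, mismatch −1, gap open −2, extend −0.5);
alignment identity below 50 % is rejected as non-CDS rather than
pseudogene. One catalog entry per distinct intact spacer, ordered by
descending representative coverage.

Relative content is estimated by mapping the *complete* library onto each
representative unit doubled head-to-tail (so junction-spanning reads map),
both strands, mismatch-only placement. A read contributes weight 1 split
equally among the references achieving the minimum mismatch count (≤2),
and only if its best placement overlaps the spacer by ≥20 bp — CDS-only
reads are uninformative. Contents are weights normalized by the total
contributing weight. Classes: major ≥0.10, minor ≥0.05, rare otherwise
(boundaries inclusive).

Two estimator biases are documented rather than corrected (no EM-style
multi-mapping resolution): (i) reads whose covered spacer window contains
no diagnostic site split their weight equally, pulling contents toward
uniform — negligible when ribotype pairs differ at ~4+ spread-out sites,
but material for low-divergence catalogs (with only 2 variant sites per
ribotype the asymptotic mean absolute error reaches ~0.05); (ii) junction
reads crossing into an unlike neighbouring copy map to no reference within
2 mismatches, which slightly depresses rare-ribotype estimates (a rare
copy's neighbours are almost always unlike). Under the documented
conditions the mean absolute content error stays below 0.02.

## Spacer features (`igsfeat`)

* GC content: (G+C)/(A+C+G+T), N excluded from both sides.
* Pairwise identity: matched columns over alignment length (or ungapped
  columns) of the optimal global affine alignment; arguments are ordered
  lexicographically before aligning so the reported value is symmetric
  under co-optimal alignments of different lengths. With
  `mask_long_indels`, gap runs longer than 5 bp are removed from numerator
  and denominator — spacer evolution repeatedly gains and loses long
  indels, and masking them reads the substitution-level similarity.
* Tandem duplications: exact 15-mer self-matches at offset ≥ `min_unit`
  (default 30) are clustered by diagonal (drift ≤20 bp absorbs inter-copy
  indels), refined by ungapped X-drop extension, then copy boundaries are
  refined by divergence parsimony over ±6 bp (a chance context match can
  drag the ungapped extension past the true boundary). The unit length is
  the offset between adjacent copy starts; copies must be adjacent
  (gap ≤5 bp) and diverge ≤20 % (substituted + indel bases per unit);
  further adjacent copies are absorbed greedily. The search runs on the
  full unit so duplications spanning the CDS 3′ end split correctly into
  CDS-derived and spacer-derived portions.
* Motif scan: upstream offsets count −1 as the spacer base immediately 5′
  of the downstream CDS start. Defaults: `TTTAATA` at −30 (window ±5, ≤1
  mismatch), `GC` at −12 and −14 (±2, exact), `GA` at −3 (±2, exact),
  pyrimidine (IUPAC `Y`) at −1 (exact), terminator `TTTTT` within the
  first 15 bp of the spacer 5′ end. The reported hit is the closest to the
  expected offset among those with fewest mismatches.
* Structural variants: a query spacer is globally aligned to a master
  reference carrying all three signature segments (group-specific indels I
  and II, GC duplication); a segment is present iff ≥50 % of its columns
  align to query bases; identity <40 % is rejected as not comparable.
  Labels: I∧II → A, I alone → B, II alone → C (without GC-DUP) or D (with),
  neither indel → unclassified. The shipped reference alignment and
  signature coordinates are synthetic (marked `.synthetic.`; the GC
  duplication is represented by an 8-bp segment so alignment can localize
  it — a literal 2-bp `GC` cannot be placed unambiguously); real
  coordinates are supplied via the same YAML.

## Haplotype networks (`hapnet`)

Distances count gaps as a fifth character state — aligned spacers are
indel-rich and ignoring gap columns would erase exactly the signal the
networks display. Feasible links are the minimum-spanning network: a pair
is linked iff its distance is within ε (default 0) of the bottleneck
(minimax-path) distance, computed over a deterministic Kruskal MST. The
median-joining iteration adds, among all quasi-medians of mutually linked
triplets (column-majority; fully ambiguous columns expand over the three
states, capped at 8 such columns), the candidate giving the largest total
cost reduction (ties by sequence), deletes median nodes whose removal does
not raise the cost, and repeats to fixpoint. The final cost never exceeds
the initial spanning-network cost; note that it can exceed the plain MST
weight (three pairwise-equidistant haplotypes with no cost-reducing median
keep their triangle), so the MST is a reference point, not a bound.
Clusters are connected components after removing edges heavier than a
threshold (default 3), labeled by their smallest member.

`align_small` is a deterministic center-star progressive aligner (center =
maximum summed pairwise score, ties by id; merge by once-a-gap-always-a-
gap) intended for catalog-sized sets (≤200); induced pairwise identities
are within a few points of the pairwise optima on near-identical spacers.

## Determinism and problem sizes

Every random draw derives from a single integer seed through named
substreams; identical configuration and seed give byte-identical pipeline
output trees (verified by manifest hash). Test and acceptance runs use
20-copy arrays (100 copies for the off-boundary classification check) at
100× with 250-bp reads — small enough that the full suite runs in well
under a minute while every per-ribotype signal (down to 2 copies) stays
far above the noise thresholds derived above.

## Known limitations

* Phasing requires reads spanning adjacent variant sites; spacers whose
  variant sites are farther apart than the read span (or libraries much
  shorter than the spacer) are reported as ambiguous path sets, not
  resolved.
* The map-back estimator's equal-split rule biases contents toward uniform
  for low-divergence catalogs (see above); contents for ribotypes whose
  true share sits exactly on a class boundary classify either way under
  sampling noise.
* Pseudogene copies whose CDS mutations fall inside the chosen anchor
  unitig can escape unit-level detection when many CDS variants coexist.
* Table-style reproduction of published per-species spacer statistics
  requires the deposited clone sequences; the feature operations are
  exercised on synthetic constructions instead.
* Real Illumina error structure (quality decay, indel errors, duplicates)
  is not simulated; the error model is i.i.d. substitutions.
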