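# Methods

## Coordinate and junction conventions

All public coordinates are 1-based inclusive; "north" is the
lower-coordinate end of the chromosome. A deletion is described by the last
retained base before the lesion (`north_bp`) and the first retained base
after it (`south_bp`), so `deletion_size = south_bp − north_bp − 1`
independently of any filler DNA inserted at the junction. BED and bedGraph
exports are 0-based half-open; the conversion lives in exactly two
functions in `breakscan.io` to prevent off-by-one drift.

Microhomology is reported as the longest sequence shared by the start of
the deleted north segment and the start of the retained south flank
("donor-junction homology"). For a blunt junction this coincides with the
anchor-overlap definition and makes the breakpoint placement ambiguous; the
north-most (left-aligned) placement is reported, the common convention in
structural-variant calling. For a filler junction the homology does not
create placement ambiguity and is reported alongside the filler; the two
never claim the same junction bases.

## Junction mapping model

`map_junction` is exact-match anchor extension, not scored alignment: the
reads this pipeline consumes are in-silico PCR products whose flanks match
the reference base for base (the wet-lab analogue is a Sanger-verified
junction). The longest exact prefix and suffix of the read that occur in
the reference are found by binary search over the prefix length (each probe
is a single substring scan); a side is mappable only if its maximal
extension is at least `min_anchor` (default 20 nt) long and occurs exactly
once. This uniqueness rule is what makes repeat-flank junctions come back
*unmappable* rather than wrongly placed: inside a perfect tandem array
every period-shifted placement of the anchor is equally good.

Consequences worth knowing:

* A read whose repeat-derived arm chance-extends one base further at a
  single placement would be spuriously "unique". The synthetic fixtures
  therefore guarantee single-base distinctness at every junction (below);
  on real data the caller should treat a barely-unique anchor with
  suspicion.
* With filler present, anchors stop at the junction only if the filler does
  not begin/end with the next reference base; when it does, filler bases
  are indistinguishable from flank bases and the reported filler is
  correspondingly shorter. This is a property of the junction itself, not
  of the algorithm.

## The pipeline

Phase 1 amplifies every panel primer pair on every genome (exact-match
binding, both orientations, smallest product under a 5 kbp ceiling,
multiplicity flagged). Primers that fail to amplify the parent are masked
as uninformative; informative-absent amplicons define the minimal deleted
interval (their union span) and the nearest informative-present amplicons
bound the maximal one. These bounds assume no amplicon straddles a true
junction — a straddling amplicon is neither cleanly present nor cleanly
absent — so panel designs (including the fixture generator's) avoid
placing amplicons across candidate breakpoints; with sparse tilings this is
the overwhelmingly common case anyway.

Phase 2 emulates iterative blot hybridization: the first retained base
south of the lesion is located by binary search on "does this parent probe
window occur in the mutant?", which is monotone for a contiguous deletion
once the search starts inside the certainly-deleted interval. A probe
window just south of that boundary is then screened against a built-in
table of eight palindromic 6-cutters; enzymes whose probe-fragment size
multiset differs between parent and mutant are RFLP hits, sorted by
smallest mutant fragment.

Phase 3 circularizes the mutant fragment containing the probe and predicts
the inverse-PCR product through the fragment's doubled string, from the
forward primer around the ligation seam to the reverse primer's site.
Phase 4 maps the junction-spanning part of that product. Two practical
rules: (i) the pipeline reads only a bounded, primer-proximal stretch of
the product (`read_length`, default 800 nt; 380 on the scaled fixture) —
the in-silico analogue of a sequencing read. This matters for repeat-flank
junctions: an unbounded read would eventually reach unique sequence beyond
the repeat and "rescue" a junction that a finite read cannot resolve.
(ii) if the chosen enzyme cuts too close to the junction and truncates an
anchor, the next RFLP-positive enzyme is tried; a one-sided call is
accepted only when no enzyme resolves both sides.

Phase 5 designs validation primers ~half the target product size away from
each breakpoint (sliding outward/inward in 3-nt steps until both primers
are unique in reference and mutant; the slide window keeps products within
±25% of the 800 nt target) and requires the mutant product to equal
reference-north-flank + filler + reference-south-flank exactly. Phase 6
extracts 2×1 kbp donor windows per breakpoint and runs the feature
scanners; fillers of ≥10 nt are searched against decoy genomes by
exhaustive sliding identity on both strands.

For alleles with an unmappable north side the pipeline reports the
phase-1-derived bound `south_bp − (end of nearest informative PCR-positive
amplicon north of the absent run)`, the same arithmetic a bench analysis
uses ("south breakpoint to first positive fragment"). Note this counts the
uncharted gap between the last negative and first positive amplicon, so it
can exceed the true deletion size; it is a delimitation of the lesion
region, not a certified minimum, and the structured report records the
formula next to the number.

## The synthetic fixture

The default reference is a 6.0 Mbp chromosome with 64% A+T background
(Arabidopsis-like) carrying: three satellite arrays (178 bp monomer,
perfect tandem within an array, monomers of different arrays diverged
~10%), three (AG)n tracts and one (CT)n tract, three transposon-remnant
copies diverged ~5% pairwise, one 1.2 kbp A/T-rich tract seeded with ATTA
motifs every 120 bp (80% A+T), and annotated unique segments at every
junction flank. Divergence within a copy group is implemented as each copy
independently mutated at half the declared group divergence from a shared
ancestor, so pairwise identities fall in [0.80, 0.95] for the default 10%
setting.

The five allele models anchor the exact deletion sizes and the bp-2 south
coordinate as ground truth; north coordinates are chosen so all five south
breakpoints cluster in an ~83 kbp window and the two repetitive-flank
alleles break ≥500 bp inside a satellite array (bp-2) or an (AG)n tract
(bp-1). Because exact-match anchoring is brittle to single-base
coincidences, the generator enforces junction distinctness after planting:
the first base on each side of every junction genuinely mismatches its
alternative, planted microhomology terminates after exactly its declared
length, and the base following each dispersed repeat copy differs from the
first retained south base (so no end-of-repeat anchor placement can
out-extend the others). All edits touch deleted or immediately-adjacent
bases before mutants, primers or decoys are derived, so the fixture is
self-consistent for any seed.

The primer panel tiles 4.2–5.4 Mbp at 40 kbp spacing (900 bp amplicons),
dropping tiles whose primers bind non-uniquely (which silently removes
tiles inside repeats), plus two random "decoy" pairs absent from every
genome that emulate parent-polymorphic loci. A 100× scaled-down fixture
(60 kbp, 400 bp tiling, 300 bp amplicons) preserves the qualitative
structure — including the repeat-flank ambiguity — for fast tests.

What the fixture does *not* emulate: sequencing error, flank divergence
between ecotypes, non-palindromic or methylation-sensitive enzymes,
incomplete digestion/ligation, PCR mispriming with mismatches, and real
satellite higher-order structure. Tests passing on the fixture therefore
demonstrate the logic of the six-phase strategy and its failure modes on
ideal substrates, not robustness to noisy reads or diverged references.

## Feature scanners and summaries

All scanners are perfect-match and N-breaking. A/T content uses a sliding
window (default 50 nt, flag threshold 0.75 — the standard display for
A/T-rich fragile-site plots). Tandem repeats are maximal perfect arrays of
primitive units up to 6 nt with ≥4 copies; phase-rotated reports of one
periodic run are collapsed and units canonicalized to their smallest
rotation; a trailing partial unit is excluded so span = copies × unit.
Inverted repeats report maximal stems ≥10 nt with loops ≤20 nt whose loop
cannot itself pair inward (so each hairpin is reported once, at its
narrowest loop); this geometric rule deliberately replaces thermodynamic
folding. MAR propensity is a declared, simple rule — window 300 nt, A/T ≥
0.70, ≥2 ATTA/ATTTA motif hits on either strand, adjacent candidate
windows merged — standing in for dedicated MAR predictors, and its
thresholds are constants, not fitted values.

Chromatin fractions normalize per-mark IP/input log ratios by their sum;
negative ratios are clamped to zero by default (fractions must be
non-negative for a pie-style summary) with a toggle to sum raw values,
since either reading of the source convention is defensible. Interorigin
statistics are successive-gap mean/median (midpoint convention for even
counts), plus the bracketing-gap lookup for a region of interest.

## Numerical and engineering choices

Sequences are Python strings scanned with C-speed substring search; the
6 Mbp pipeline run completes in ~20 s on one CPU and the scaled fixture in
well under a second, which is why the default test suite exercises the
scaled fixture everywhere and reserves one module-scoped full-size run for
the acceptance-level checks. Determinism: every random choice flows from a
single integer seed through numpy Generators; identical seeds produce
byte-identical fixtures and reports. Zero-length restriction fragments
from adjacent cut sites are retained so fragment lengths always sum to the
genome length. Ties in amplification (multiple convergent sites) resolve
to the smallest product, flagged as multiple. The repair-signature
threshold for calling microhomology is 2 nt so single-base chance matches
do not trigger the flag.

## Known limitations

* Exact-match primer binding and anchoring: no mismatch tolerance
  anywhere; diverged templates (ecotype polymorphism) appear simply as
  absent products, which is how the informativeness masking treats them.
* Single contiguous deletions only: non-contiguous absent runs are flagged
  ("possible complex lesion"), not decomposed; inversions and
  translocations are out of scope.
* The minimal-deletion bound for unmappable-flank alleles delimits the
  lesion region using the tiling resolution (see above); it is not a
  certified lower bound on the deleted length.
* MAR propensity and hairpin geometry are declared simplifications; their
  outputs are qualitative annotations, not predictions calibrated against
  any experimental dataset.
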