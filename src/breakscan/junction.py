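"""Phases 4-6 core: junction mapping, repair classification, validation.

Junction mapping is exact-match anchor extension, not scored alignment: the
junction reads this pipeline consumes are in-silico PCR products (and the
wet-lab analogue is Sanger-sequenced), so flanks match the reference
base-for-base.  A side is mappable only when the maximal exact extension of
its anchor occurs exactly once in the reference; breakpoints inside
dispersed or tandem repeats therefore come back unmappable rather than
wrongly placed.

Breakpoint reporting convention: ``north_bp`` = last retained base,
``south_bp`` = first retained base, ``deletion_size = south_bp - north_bp - 1``.
When microhomology makes the placement ambiguous the north-most (left-most)
equivalent placement is reported, the common convention in structural-variant
calling.  Microhomology itself is reported as the longest sequence shared by
the start of the deleted north segment and the start of the retained south
flank (donor-junction homology), which for a blunt junction coincides with
the anchor-overlap definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    count_occurrences,
    find_all,
    longest_prefix_in,
    longest_suffix_in,
    revcomp,
)
from .errors import (
    BreakscanError,
    DataError,
    NoJunctionError,
    RepetitiveFlankError,
    RepetitiveJunctionError,
)
from .genome import DonorPair, Genome, PrimerPair
from .pcr import amplify

_MH_CAP = 100


@dataclass
class JunctionCall:
    """A mapped deletion junction (see module docstring for conventions)."""

    allele: str
    north_bp: int | None
    south_bp: int | None
    filler: str
    microhomology: str
    north_mappable: bool
    south_mappable: bool
    repair_flags: set[str] = field(default_factory=set)

    @property
    def deletion_size(self) -> int | None:
        if self.north_bp is None or self.south_bp is None:
            return None
        return self.south_bp - self.north_bp - 1

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "north_bp": self.north_bp,
            "south_bp": self.south_bp,
            "deletion_size": self.deletion_size,
            "filler": self.filler,
            "microhomology": self.microhomology,
            "north_mappable": self.north_mappable,
            "south_mappable": self.south_mappable,
            "repair_flags": sorted(self.repair_flags),
        }


def _donor_homology(seq: str, north_bp: int, south_bp: int) -> str:
    """Longest common prefix of the deleted north start and the south flank."""
    out = []
    for k in range(_MH_CAP):
        i, j = north_bp + k, south_bp - 1 + k  # 0-based of ref[nb+1+k], ref[sb+k]
        if j >= len(seq) or i >= south_bp - 1 or seq[i] != seq[j]:
            break
        out.append(seq[i])
    return "".join(out)


def map_junction(
    read: str, reference: Genome, min_anchor: int = 20, allele: str = ""
) -> JunctionCall:
    """Map a junction-spanning read back to the reference.

    Finds the longest exact prefix and suffix of the read that occur in the
    reference; a side whose maximal extension is shorter than ``min_anchor``
    or occurs more than once is unmappable.  The unmatched middle of the
    read is filler; an overlap between the two anchors is microhomology and
    the call is left-aligned.
    """
    read = read.upper()
    seq = reference.sequence
    n = len(read)
    if n < 2 * min_anchor:
        raise DataError("read shorter than twice the anchor length")

    lp = longest_prefix_in(seq, read)
    if lp == n and count_occurrences(seq, read, limit=1):
        raise NoJunctionError("no junction: read aligns contiguously to reference")
    ls = longest_suffix_in(seq, read)

    north_sites = find_all(seq, read[:lp], limit=2) if lp >= min_anchor else []
    south_sites = find_all(seq, read[n - ls :], limit=2) if ls >= min_anchor else []
    north_ok = len(north_sites) == 1
    south_ok = len(south_sites) == 1
    if not north_ok and not south_ok:
        raise RepetitiveJunctionError("repetitive junction: both anchors ambiguous")

    if north_ok and south_ok:
        p0 = north_sites[0] + 1  # 1-based ref start of the prefix anchor
        s0 = south_sites[0] + 1  # 1-based ref start of the suffix anchor
        i_min, i_max = n - ls, lp  # valid read split indices
        if i_max < i_min:  # filler separates the anchors
            filler = read[lp : n - ls]
            north_bp, south_bp = p0 + lp - 1, s0
        elif i_max == i_min:  # blunt
            filler = ""
            north_bp, south_bp = p0 + lp - 1, s0
        else:  # anchors overlap: left-align the junction
            filler = ""
            north_bp, south_bp = p0 + i_min - 1, s0
        size = south_bp - north_bp - 1
        if size < 1 and not filler:
            raise NoJunctionError("no junction: anchors are contiguous on reference")
        if size < 0:
            raise NoJunctionError("inconsistent anchor placements")
        mh = _donor_homology(seq, north_bp, south_bp)
        return JunctionCall(
            allele, north_bp, south_bp, filler, mh,
            north_mappable=True, south_mappable=True,
        )

    if south_ok:
        return JunctionCall(
            allele, None, south_sites[0] + 1, "", "",
            north_mappable=False, south_mappable=True,
        )
    return JunctionCall(
        allele, north_sites[0] + lp - 1 + 1, None, "", "",
        north_mappable=True, south_mappable=False,
    )


def classify_repair(call: JunctionCall, mh_threshold: int = 2) -> set[str]:
    """NHEJ signature flags: filler_insertion, microhomology, blunt_nhej.

    ``mh_threshold`` (default 2 nt) keeps single-base chance matches from
    being flagged as microhomology.
    """
    if not (call.north_mappable and call.south_mappable):
        raise BreakscanError("cannot classify: a junction side is unmappable")
    flags: set[str] = set()
    if call.filler:
        flags.add("filler_insertion")
    if len(call.microhomology) >= mh_threshold:
        flags.add("microhomology")
    if not flags:
        flags.add("blunt_nhej")
    call.repair_flags = flags
    return flags


def _unique_in(seq: str, primer: str) -> bool:
    return (
        count_occurrences(seq, primer, limit=2) == 1
        and count_occurrences(seq, revcomp(primer), limit=1) == 0
    )


def design_validation_primers(
    call: JunctionCall,
    reference: Genome,
    mutant: Genome,
    target_size: int = 800,
    primer_len: int = 20,
) -> PrimerPair:
    """Phase-5 primers flanking the junction, unique in reference and mutant.

    The pair amplifies the mutant across the junction with a product within
    +-25% of ``target_size``; on the reference the same pair spans the whole
    deletion and (for the deletion sizes of interest) exceeds any realistic
    PCR ceiling.  Candidate positions slide away from the junction until
    both primers are unique in both genomes.
    """
    if not (call.north_mappable and call.south_mappable):
        raise RepetitiveFlankError("flank too repetitive: junction side unmappable")
    if target_size < 2 * primer_len + len(call.filler) + 2:
        raise DataError("target_size smaller than the primers themselves")
    arm = (target_size - len(call.filler)) // 2
    slack = max(4, target_size // 8)  # keeps the product within +-25% of target

    def _pick(anchor_start: int, north_side: bool) -> str | None:
        for off in range(0, slack, 3):
            start = anchor_start + (off if north_side else -off)
            end = start + primer_len - 1
            if start < 1 or end > len(reference):
                continue
            cand = reference.sub(start, end)
            primer = cand if north_side else revcomp(cand)
            if _unique_in(reference.sequence, cand) and _unique_in(
                mutant.sequence, cand
            ):
                return primer
        return None

    fwd = _pick(call.north_bp - arm + 1, north_side=True)
    rev = _pick(call.south_bp + arm - primer_len, north_side=False)
    if fwd is None or rev is None:
        raise RepetitiveFlankError("flank too repetitive: no unique primer in window")
    return PrimerPair(f"val-{call.allele or 'junction'}", fwd, rev)


@dataclass
class ValidationResult:
    passed: bool
    product: str
    reason: str = ""


def validate_junction(
    mutant: Genome,
    pair: PrimerPair,
    call: JunctionCall,
    reference: Genome,
    max_product: int = 5_000,
) -> ValidationResult:
    """Phase 5: the pair must amplify the mutant into the predicted sequence.

    The expected product is reconstructed from the reference flanks plus the
    filler; a pass requires an in-silico product that matches it
    base-for-base (which implies it contains the filler exactly).
    """
    amp = amplify(mutant, pair, max_product=max_product)
    if amp.status == "absent":
        return ValidationResult(False, "", "no product")
    product = mutant.sub(amp.start, amp.end)
    fwd_sites = find_all(reference.sequence, pair.fwd, limit=2)
    rev_sites = find_all(reference.sequence, revcomp(pair.rev), limit=2)
    if len(fwd_sites) != 1 or len(rev_sites) != 1:
        return ValidationResult(False, product, "primers not unique in reference")
    fwd_start = fwd_sites[0] + 1
    rev_end = rev_sites[0] + len(pair.rev)
    if not (fwd_start <= call.north_bp and rev_end >= call.south_bp):
        return ValidationResult(False, product, "primers do not flank the junction")
    expected = (
        reference.sub(fwd_start, call.north_bp)
        + call.filler
        + reference.sub(call.south_bp, rev_end)
    )
    if product != expected:
        return ValidationResult(False, product, "sequence mismatch")
    return ValidationResult(True, product)


def extract_donors(
    reference: Genome, call: JunctionCall, flank: int = 1_000
) -> DonorPair:
    """Donor windows: retained flank + adjacent deleted flank on each side.

    north_donor = reference[north_bp-flank+1 .. north_bp+flank]
    south_donor = reference[south_bp-flank .. south_bp+flank-1]
    (truncated at chromosome ends, with a note).
    """
    if call.north_bp is None or call.south_bp is None:
        raise DataError("both breakpoints required to extract donors")
    notes: list[str] = []
    L = len(reference)

    def _window(lo: int, hi: int, label: str) -> str:
        clo, chi = max(1, lo), min(L, hi)
        if (clo, chi) != (lo, hi):
            notes.append(f"{label} donor truncated at chromosome end")
        return reference.sub(clo, chi)

    north = _window(call.north_bp - flank + 1, call.north_bp + flank, "north")
    south = _window(call.south_bp - flank, call.south_bp + flank - 1, "south")
    return DonorPair(north, south, flank, notes)


@dataclass(frozen=True)
class FillerHit:
    genome: str
    start: int  # 1-based on the decoy's plus strand
    strand: str
    identity: float


def locate_filler_origin(
    filler: str,
    decoys: list[Genome],
    min_identity: float = 0.90,
) -> list[FillerHit]:
    """Exhaustive sliding comparison of the filler against decoy genomes.

    Both strands are scanned; every window whose per-base identity reaches
    ``min_identity`` is reported, best first.  Quadratic in nothing: the
    comparison is vectorized per filler position, O(|filler| * |decoy|).
    """
    if len(filler) < 10:
        raise DataError("filler shorter than 10 nt")
    m = len(filler)
    farr = np.frombuffer(filler.encode("ascii"), dtype=np.uint8)
    hits: list[FillerHit] = []
    for decoy in decoys:
        L = len(decoy.sequence)
        if L < m:
            continue
        for strand, seq in (("+", decoy.sequence), ("-", revcomp(decoy.sequence))):
            darr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            nwin = L - m + 1
            matches = np.zeros(nwin, dtype=np.int32)
            for k in range(m):
                matches += darr[k : k + nwin] == farr[k]
            for off in np.flatnonzero(matches >= np.ceil(min_identity * m)):
                off = int(off)
                start = off + 1 if strand == "+" else L - off - m + 1
                hits.append(FillerHit(decoy.name, start, strand, matches[off] / m))
    hits.sort(key=lambda h: (-h.identity, h.genome, h.start))
    return hits
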