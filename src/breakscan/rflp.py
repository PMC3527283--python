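"""Phases 2-3: restriction digestion, RFLP discovery, inverse-PCR prediction.

Sites are recognized on the plus strand only; the built-in enzyme table is
restricted to palindromic 6-cutters, for which plus-strand recognition is
equivalent to double-stranded recognition.  Digestion is linear (the
chromosome is not a circle); circularity enters only in
:func:`ipcr_predict`, where a single restriction fragment is treated as
re-ligated into a circle and scanned via its doubled string.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import find_all
from .errors import DataError
from .genome import Enzyme, Genome, PrimerPair

BUILTIN_ENZYMES: list[Enzyme] = [
    Enzyme("EcoRI", "GAATTC", 1),
    Enzyme("BamHI", "GGATCC", 1),
    Enzyme("HindIII", "AAGCTT", 1),
    Enzyme("XbaI", "TCTAGA", 1),
    Enzyme("SalI", "GTCGAC", 1),
    Enzyme("XhoI", "CTCGAG", 1),
    Enzyme("PstI", "CTGCAG", 5),
    Enzyme("KpnI", "GGTACC", 5),
]


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment, on source-genome 1-based coordinates."""

    start: int
    end: int  # inclusive; end == start - 1 encodes a zero-length fragment
    sequence: str

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class FragmentSet:
    """Ordered, contiguous fragments that concatenate to the source genome."""

    source: str
    fragments: list[Fragment]

    def containing(self, pos: int) -> Fragment:
        for f in self.fragments:
            if f.start <= pos <= f.end:
                return f
        raise DataError(f"position {pos} not covered by any fragment")

    def overlapping(self, start: int, end: int) -> list[Fragment]:
        return [f for f in self.fragments if f.start <= end and f.end >= start]


def digest(genome: Genome, enzyme: Enzyme) -> FragmentSet:
    """Cut at every exact plus-strand site occurrence, linearly.

    The cut falls ``cut_offset`` nt after the site start; adjacent sites may
    produce zero-length fragments, which are retained so that fragment
    lengths always sum to the genome length.
    """
    seq = genome.sequence
    cuts = sorted(i + enzyme.cut_offset for i in find_all(seq, enzyme.site))
    cuts = [c for c in cuts if 0 < c < len(seq)]
    bounds = [0, *cuts, len(seq)]
    frags = [
        Fragment(a + 1, b, seq[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    assert sum(f.size for f in frags) == len(seq)
    return FragmentSet(genome.name, frags)


@dataclass(frozen=True)
class RflpHit:
    """An enzyme showing a parent/mutant fragment-size difference at a probe."""

    enzyme: Enzyme
    parent_sizes: tuple[int, ...]
    mutant_sizes: tuple[int, ...]  # empty when the probe is absent from the mutant

    @property
    def smallest_mutant(self) -> int | None:
        return min(self.mutant_sizes) if self.mutant_sizes else None


def find_rflp(
    parent: Genome,
    mutant: Genome,
    enzymes: list[Enzyme],
    probe_region: tuple[int, int],
) -> list[RflpHit]:
    """Find enzymes whose probe-fragment size multiset differs between genomes.

    For each enzyme: the parent fragments overlapping ``probe_region`` are
    compared with the mutant fragments containing the (homologous) probe
    sequence.  Hits are sorted by smallest mutant fragment; enzymes whose
    probe sequence is missing from the mutant sort last with empty mutant
    sizes.
    """
    ps, pe = probe_region
    probe_seq = parent.sub(ps, pe)
    probe_hits = find_all(mutant.sequence, probe_seq)
    hits: list[RflpHit] = []
    for enzyme in enzymes:
        pset = digest(parent, enzyme)
        parent_sizes = tuple(sorted(f.size for f in pset.overlapping(ps, pe)))
        if probe_hits:
            mset = digest(mutant, enzyme)
            mutant_frags = {
                id(f): f
                for h in probe_hits
                for f in mset.overlapping(h + 1, h + len(probe_seq))
            }
            mutant_sizes = tuple(sorted(f.size for f in mutant_frags.values()))
        else:
            mutant_sizes = ()
        if sorted(parent_sizes) != sorted(mutant_sizes):
            hits.append(RflpHit(enzyme, parent_sizes, mutant_sizes))
    hits.sort(
        key=lambda h: (h.smallest_mutant is None, h.smallest_mutant or 0, h.enzyme.name)
    )
    return hits


@dataclass
class IpcrProduct:
    sequence: str
    spans_ligation: bool  # False = primers converge without wrapping

    def __bool__(self) -> bool:
        return bool(self.sequence)


def ipcr_predict(fragment: str, pair: PrimerPair) -> IpcrProduct:
    """Predict the inverse-PCR product from a circularized fragment.

    The fragment is treated as a circle (its end ligated to its start) and
    scanned through its doubled string.  The product is the plus-strand
    sequence from the forward primer's 5' end to the 3' end of the reverse
    primer's binding site, going around the circle.  A product that does not
    cross the ligation seam (ordinary PCR orientation) is returned flagged
    ``spans_ligation=False``; when the primers do not converge on the circle
    at all the product is empty.
    """
    from ._seq import revcomp  # local import avoids cycle at module load

    n = len(fragment)
    if n < len(pair.fwd) + len(pair.rev):
        raise DataError("fragment shorter than the two primers")
    doubled = fragment + fragment
    fwd_sites = [i for i in find_all(doubled, pair.fwd) if i < n]
    rc_rev = revcomp(pair.rev)
    rev_sites = [i for i in find_all(doubled, rc_rev) if i < n]
    if not fwd_sites or not rev_sites:
        return IpcrProduct("", False)
    best: tuple[int, int, int] | None = None  # (size, f, r_end)
    for f in fwd_sites:
        for r in rev_sites:
            r_end = r + len(rc_rev)  # 0-based exclusive on the circle
            if r_end <= f:
                r_end += n
            size = r_end - f
            if size < len(pair.fwd) + len(pair.rev) or size > n:
                continue
            if best is None or size < best[0]:
                best = (size, f, r_end)
    if best is None:
        return IpcrProduct("", False)
    size, f, r_end = best
    return IpcrProduct(doubled[f:r_end], spans_ligation=r_end > n)
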