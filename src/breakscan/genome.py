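"""Core domain types: genomes, feature annotations and deletion allele models.

Coordinate convention
---------------------
All coordinates in this package are **1-based and inclusive**, with "north"
being the lower-coordinate end of the chromosome (the nucleolar-organizer end
of the modelled chromosome arm).  For a deletion allele,

* ``north_bp`` is the last retained base before the deleted segment,
* ``south_bp`` is the first retained base after it, so that
* ``deletion_size = south_bp - north_bp - 1``

independently of any filler DNA inserted at the junction.  BED export
(0-based, half-open) is handled centrally in :mod:`breakscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import check_alphabet
from .errors import DataError

COORDINATE_CONVENTION = "1-based, inclusive, north = lower coordinates"

FEATURE_KINDS = (
    "satellite",
    "AG_repeat",
    "CT_repeat",
    "transposon_remnant",
    "AT_tract",
    "unique_segment",
)


@dataclass(frozen=True)
class Genome:
    """A named chromosome-scale sequence over {A,C,G,T,N}."""

    name: str
    sequence: str
    convention: str = COORDINATE_CONVENTION

    def __post_init__(self) -> None:
        check_alphabet(self.sequence, allow_n=True, what=f"genome {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def sub(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise DataError(
                f"coordinates [{start}, {end}] outside genome {self.name!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]

    def base(self, pos: int) -> str:
        return self.sub(pos, pos)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A planted feature interval on a genome (1-based inclusive)."""

    kind: str
    start: int
    end: int
    copy_group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise DataError(f"bad feature interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlleleModel:
    """Ground-truth parameters of one deletion allele.

    ``microhomology_len`` bases are planted so that the first retained bases
    south of the junction are repeated at the start of the deleted north
    segment (the donor-junction homology a junction mapper should report).
    """

    name: str
    north_bp: int
    south_bp: int
    filler: str = ""
    north_flank_class: str = "unique"
    microhomology_len: int = 0
    mutagen: str = ""

    def __post_init__(self) -> None:
        if self.north_flank_class not in ("unique", "repetitive"):
            raise DataError(
                f"north_flank_class must be unique/repetitive, got {self.north_flank_class!r}"
            )
        if self.microhomology_len < 0:
            raise DataError("microhomology_len must be >= 0")
        if self.filler:
            check_alphabet(self.filler, allow_n=False, what="filler")
        if self.north_bp < 1 or self.south_bp <= self.north_bp + 1:
            raise DataError(
                f"allele {self.name!r}: need 1 <= north_bp and north_bp + 1 < south_bp"
            )

    @property
    def deletion_size(self) -> int:
        return self.south_bp - self.north_bp - 1

    def validate_against(self, genome: Genome) -> None:
        if self.south_bp > len(genome):
            raise DataError(
                f"allele {self.name!r}: south_bp {self.south_bp} outside genome "
                f"of length {len(genome)}"
            )


def apply_allele(reference: Genome, allele: AlleleModel, name: str | None = None) -> Genome:
    """Splice a deletion allele into a reference genome.

    mutant = reference[1..north_bp] + filler + reference[south_bp..end]
    """
    if allele.south_bp <= allele.north_bp + 1:
        raise DataError("empty deletion")
    allele.validate_against(reference)
    seq = reference.sequence
    mutant = seq[: allele.north_bp] + allele.filler + seq[allele.south_bp - 1 :]
    expected = len(seq) - allele.deletion_size + len(allele.filler)
    assert len(mutant) == expected
    return Genome(name=name or allele.name, sequence=mutant)


@dataclass
class PrimerPair:
    """A forward/reverse primer pair, optionally with its expected amplicon."""

    name: str
    fwd: str
    rev: str
    expected_start: int | None = None
    expected_end: int | None = None

    def __post_init__(self) -> None:
        self.fwd = self.fwd.upper()
        self.rev = self.rev.upper()
        check_alphabet(self.fwd, allow_n=False, what=f"primer {self.name!r} fwd")
        check_alphabet(self.rev, allow_n=False, what=f"primer {self.name!r} rev")
        if self.fwd == self.rev:
            raise DataError(f"primer pair {self.name!r}: fwd and rev are identical")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: plus-strand recognition site and cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        check_alphabet(self.site, allow_n=False, what=f"enzyme {self.name!r} site")
        if not 0 <= self.cut_offset <= len(self.site):
            raise DataError(
                f"enzyme {self.name!r}: cut_offset must lie within the site"
            )


@dataclass
class DonorPair:
    """Junction donor sequences: retained + deleted flank on each side."""

    north_donor: str
    south_donor: str
    flank: int
    notes: list[str] = field(default_factory=list)
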