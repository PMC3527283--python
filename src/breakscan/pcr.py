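"""In-silico PCR: primer binding, amplification, and the allele x primer matrix.

Primer binding is exact-match only: a mismatch model would introduce
annealing parameters that nothing in the deletion-scanning problem
constrains.  A product is called wherever a forward site and a
reverse-complement site face each other within ``max_product``; when several
convergent placements exist the smallest product is reported, flagged as
multiple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import check_alphabet, find_all, revcomp
from .errors import DataError
from .genome import Genome, PrimerPair


@dataclass(frozen=True)
class AmpliconCall:
    """One genome x primer-pair amplification outcome.

    status 'present': a product of ``size`` nt at [start, end];
    'aflp': template present but product size differs from the parent;
    'absent': no convergent primer placement within the size ceiling.
    """

    status: str
    size: int | None = None
    start: int | None = None
    end: int | None = None
    multiple: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("present", "absent", "aflp"):
            raise DataError(f"bad amplicon status {self.status!r}")
        if self.status == "absent" and self.size is not None:
            raise DataError("absent call cannot carry a size")
        if self.status in ("present", "aflp") and self.size is None:
            raise DataError(f"{self.status} call requires a size")

    def as_cell(self) -> str:
        if self.status == "absent":
            return "absent"
        return f"{self.status}:{self.size}"


def find_binding_sites(genome: Genome, primer: str) -> list[tuple[int, str]]:
    """Every exact binding site of a primer, as (1-based start, strand).

    A '+' hit is an occurrence of the primer itself; a '-' hit is an
    occurrence of its reverse complement (the primer anneals to the plus
    strand and extends toward lower coordinates).  Starts refer to the plus
    strand and the list is sorted by start.
    """
    primer = primer.upper()
    check_alphabet(primer, allow_n=False, what="primer")
    if len(primer) < 10:
        raise DataError("primer shorter than 10 nt")
    hits = [(i + 1, "+") for i in find_all(genome.sequence, primer)]
    rc = revcomp(primer)
    hits += [(i + 1, "-") for i in find_all(genome.sequence, rc)]
    return sorted(hits)


def _convergent_products(
    seq: str, left: str, right_rc: str, max_product: int
) -> list[tuple[int, int, int]]:
    """(size, start, end) for every left-site ... rc(right)-site pairing."""
    out = []
    lefts = find_all(seq, left)
    rights = find_all(seq, right_rc)
    min_size = len(left) + len(right_rc)
    j0 = 0
    for f in lefts:
        for r in rights[j0:]:
            end = r + len(right_rc)  # 0-based exclusive
            size = end - f
            if size < min_size:
                continue
            if size <= max_product:
                out.append((size, f + 1, end))
    return out


def amplify(genome: Genome, pair: PrimerPair, max_product: int = 5_000) -> AmpliconCall:
    """Predict the PCR outcome of one primer pair on one genome.

    Both orientations of the template are considered (fwd on plus with rev
    on minus, and the mirror image), so the call is invariant under
    reverse-complementing the genome and swapping the primers.
    """
    seq = genome.sequence
    products = _convergent_products(seq, pair.fwd, revcomp(pair.rev), max_product)
    products += _convergent_products(seq, pair.rev, revcomp(pair.fwd), max_product)
    if not products:
        return AmpliconCall("absent")
    products.sort()
    size, start, end = products[0]
    return AmpliconCall("present", size, start, end, multiple=len(products) > 1)


@dataclass
class AmpliconMatrix:
    """Genome-label x primer-name table of AmpliconCalls (rectangular)."""

    rows: list[str]
    cols: list[str]
    calls: dict[tuple[str, str], AmpliconCall] = field(default_factory=dict)
    parent_label: str | None = None

    def __getitem__(self, key: tuple[str, str]) -> AmpliconCall:
        return self.calls[key]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: [self.calls[(r, c)].as_cell() for r in self.rows] for c in self.cols},
            index=self.rows,
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="genome")


def build_amplicon_matrix(
    genomes: list[Genome],
    panel: list[PrimerPair],
    parent_label: str,
    max_product: int = 5_000,
) -> AmpliconMatrix:
    """Amplify every pair on every genome; relabel size polymorphisms 'aflp'.

    A non-parent cell becomes 'aflp' when both it and the parent cell are
    present but with different product sizes (template retained, size
    polymorphic).
    """
    labels = [g.name for g in genomes]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate genome labels")
    if parent_label not in labels:
        raise DataError(f"parent label {parent_label!r} not among genomes")
    matrix = AmpliconMatrix(
        rows=labels, cols=[p.name for p in panel], parent_label=parent_label
    )
    for g in genomes:
        for p in panel:
            matrix.calls[(g.name, p.name)] = amplify(g, p, max_product)
    for g in genomes:
        if g.name == parent_label:
            continue
        for p in panel:
            parent = matrix.calls[(parent_label, p.name)]
            cell = matrix.calls[(g.name, p.name)]
            if (
                parent.status == "present"
                and cell.status == "present"
                and cell.size != parent.size
            ):
                matrix.calls[(g.name, p.name)] = AmpliconCall(
                    "aflp", cell.size, cell.start, cell.end, cell.multiple
                )
    return matrix
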