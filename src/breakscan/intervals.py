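"""Phase-1 interval logic: from an amplicon matrix row to deletion bounds.

A primer is *informative* for an allele only when the parent genome yields a
product for it; parent-absent primers (ecotype-polymorphic loci) carry no
evidence either way.  Informative-absent amplicons certainly overlap the
deletion, so their union span is the minimal ("inner") deletion interval;
the nearest informative-present amplicons on each side bound the maximal
("outer") one.  Amplicon coordinates are the parent's product coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError, UninformativePanelError
from .pcr import AmpliconMatrix


@dataclass(frozen=True)
class Informativeness:
    informative: bool
    evidence: str  # "deleted", "retained", "retained (polymorphic size)", "none"


@dataclass
class DeletionInterval:
    """Minimal (inner) and maximal (outer) deletion intervals for one allele.

    ``inner`` is a closed 1-based interval (or None when no informative
    amplicon is absent).  ``outer`` is an *open* interval: its endpoints are
    the end of the nearest informative-present amplicon north of the absent
    run and the start of the nearest one south of it (or chromosome ends,
    noted).  min_size / max_size follow the breakpoint convention
    size = south - north - 1.
    """

    allele: str
    inner: tuple[int, int] | None
    outer: tuple[int, int]
    n_informative: int
    note: str = ""

    @property
    def min_size(self) -> int:
        if self.inner is None:
            return 0
        return self.inner[1] - self.inner[0] + 1

    @property
    def max_size(self) -> int:
        return self.outer[1] - self.outer[0] - 1


def classify_informative(
    matrix: AmpliconMatrix, parent_label: str
) -> dict[tuple[str, str], Informativeness]:
    """Per (allele row, primer) informativeness relative to the parent row.

    Parent 'aflp' cells (possible when the matrix was built against an
    external baseline) still prove the locus amplifies in the parent and are
    treated as informative.
    """
    if parent_label not in matrix.rows:
        raise DataError(f"parent row {parent_label!r} missing from matrix")
    out: dict[tuple[str, str], Informativeness] = {}
    for row in matrix.rows:
        if row == parent_label:
            continue
        for col in matrix.cols:
            parent = matrix[(parent_label, col)]
            cell = matrix[(row, col)]
            if parent.status == "absent":
                out[(row, col)] = Informativeness(False, "none")
            elif cell.status == "absent":
                out[(row, col)] = Informativeness(True, "deleted")
            elif cell.status == "aflp" or (
                cell.status == "present" and cell.size != parent.size
            ):
                out[(row, col)] = Informativeness(True, "retained (polymorphic size)")
            else:
                out[(row, col)] = Informativeness(True, "retained")
    return out


def infer_deletion_interval(
    matrix: AmpliconMatrix,
    allele: str,
    parent_label: str,
    genome_length: int,
) -> DeletionInterval:
    """Convert one allele's matrix row into inner/outer deletion intervals.

    Coordinates come from the parent's amplicons (the reference frame).
    Non-contiguous absent runs are not split into separate events: the
    smallest enclosing interval is reported with a "possible complex lesion"
    note, since a single contiguous deletion is the model here.
    """
    info = classify_informative(matrix, parent_label)
    if allele not in matrix.rows:
        raise DataError(f"allele {allele!r} missing from matrix")

    absent: list[tuple[int, int, str]] = []
    present: list[tuple[int, int, str]] = []
    n_informative = 0
    for col in matrix.cols:
        cls = info[(allele, col)]
        if not cls.informative:
            continue
        n_informative += 1
        pcall = matrix[(parent_label, col)]
        coords = (pcall.start, pcall.end, col)
        if cls.evidence == "deleted":
            absent.append(coords)
        else:
            present.append(coords)
    if n_informative == 0:
        raise UninformativePanelError(f"uninformative panel for allele {allele!r}")

    notes: list[str] = []
    if not absent:
        return DeletionInterval(
            allele,
            inner=None,
            outer=(0, 1),
            n_informative=n_informative,
            note="no deletion evidence",
        )

    inner = (min(s for s, _, _ in absent), max(e for _, e, _ in absent))
    inside_present = [p for p in present if p[0] >= inner[0] and p[1] <= inner[1]]
    if inside_present:
        notes.append("possible complex lesion")

    north_cands = [e for s, e, _ in present if e < inner[0]]
    south_cands = [s for s, _e, _ in present if s > inner[1]]
    if north_cands:
        north_bound = max(north_cands)
    else:
        north_bound = 0
        notes.append("north bound unresolved")
    if south_cands:
        south_bound = min(south_cands)
    else:
        south_bound = genome_length + 1
        notes.append("south bound unresolved")

    return DeletionInterval(
        allele,
        inner=inner,
        outer=(north_bound, south_bound),
        n_informative=n_informative,
        note="; ".join(notes),
    )


def intervals_to_rows(intervals: list[DeletionInterval]) -> list[dict]:
    """Serialization helper for the TSV/BED exports."""
    rows = []
    for iv in intervals:
        rows.append(
            {
                "allele": iv.allele,
                "inner_start": iv.inner[0] if iv.inner else "",
                "inner_end": iv.inner[1] if iv.inner else "",
                "outer_start": iv.outer[0],
                "outer_end": iv.outer[1],
                "min_size": iv.min_size,
                "max_size": iv.max_size,
                "note": iv.note,
            }
        )
    return rows
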