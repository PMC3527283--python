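"""Format readers/writers and the single place coordinates are converted.

Internal coordinates are 1-based inclusive everywhere in the package; BED and
bedGraph are written 0-based half-open per their standards.  Keeping the
conversion in exactly two functions prevents off-by-one drift.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .genome import AlleleModel, Enzyme, Genome, PrimerPair

FASTA_WIDTH = 60


# --- coordinate conversion (the only two places it happens) ----------------

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> BED 0-based half-open (start-1, end)."""
    if start < 1 or end < start:
        raise DataError(f"bad 1-based interval [{start}, {end}]")
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    if bed_start < 0 or bed_end <= bed_start:
        raise DataError(f"bad BED interval ({bed_start}, {bed_end})")
    return bed_start + 1, bed_end


# --- FASTA ------------------------------------------------------------------

def write_fasta(path: str | Path, genomes: list[Genome]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> list[Genome]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(Genome(rec.id, str(rec.seq).upper()))
    if not out:
        raise DataError(f"no FASTA records in {path}")
    return out


# --- BED / bedGraph ---------------------------------------------------------

def write_bed(path: str | Path, rows: list[tuple[str, int, int, str]]) -> None:
    """Rows are (chrom, start_1based, end_1based, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            b0, b1 = to_bed_interval(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = from_bed_interval(int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    return rows


def write_bedgraph(
    path: str | Path, chrom: str, values: list[tuple[int, int, float]]
) -> None:
    """Values are (start_1based, end_1based, value)."""
    with open(path, "w") as fh:
        for start, end, value in values:
            b0, b1 = to_bed_interval(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{value:g}\n")


# --- TSV tables -------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return df

ALLELE_COLUMNS = [
    "name", "north_bp", "south_bp", "filler",
    "north_flank_class", "microhomology_len", "mutagen",
]


def write_alleles_tsv(path: str | Path, alleles: list[AlleleModel]) -> None:
    df = pd.DataFrame(
        [
            [a.name, a.north_bp, a.south_bp, a.filler,
             a.north_flank_class, a.microhomology_len, a.mutagen]
            for a in alleles
        ],
        columns=ALLELE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_alleles_tsv(path: str | Path) -> list[AlleleModel]:
    df = _read_tsv(path, ALLELE_COLUMNS)
    return [
        AlleleModel(
            name=r["name"],
            north_bp=int(r["north_bp"]),
            south_bp=int(r["south_bp"]),
            filler=r["filler"],
            north_flank_class=r["north_flank_class"],
            microhomology_len=int(r["microhomology_len"]),
            mutagen=r["mutagen"],
        )
        for _, r in df.iterrows()
    ]

PANEL_COLUMNS = ["name", "fwd", "rev", "expected_start", "expected_end"]


def write_panel_tsv(path: str | Path, panel: list[PrimerPair]) -> None:
    df = pd.DataFrame(
        [
            [p.name, p.fwd, p.rev,
             "" if p.expected_start is None else p.expected_start,
             "" if p.expected_end is None else p.expected_end]
            for p in panel
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> list[PrimerPair]:
    df = _read_tsv(path, PANEL_COLUMNS)
    return [
        PrimerPair(
            name=r["name"],
            fwd=r["fwd"],
            rev=r["rev"],
            expected_start=int(r["expected_start"]) if r["expected_start"] else None,
            expected_end=int(r["expected_end"]) if r["expected_end"] else None,
        )
        for _, r in df.iterrows()
    ]


def write_enzymes_tsv(path: str | Path, enzymes: list[Enzyme]) -> None:
    df = pd.DataFrame(
        [[e.name, e.site, e.cut_offset] for e in enzymes],
        columns=["name", "site", "cut_offset"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_enzymes_tsv(path: str | Path) -> list[Enzyme]:
    df = _read_tsv(path, ["name", "site", "cut_offset"])
    return [
        Enzyme(r["name"], r["site"], int(r["cut_offset"]))
        for _, r in df.iterrows()
    ]


def read_marks_tsv(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    """Chromatin mark table: columns region, mark, log_ratio -> per-region lists."""
    df = _read_tsv(path, ["region", "mark", "log_ratio"])
    out: dict[str, list[tuple[str, float]]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["region"], []).append((r["mark"], float(r["log_ratio"])))
    return out


def read_origins(path: str | Path) -> list[int]:
    """Replication origins from BED (interval midpoints) or one-column TSV."""
    path = Path(path)
    positions: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 3:
                    start, end = from_bed_interval(int(parts[1]), int(parts[2]))
                    positions.append((start + end) // 2)
                else:
                    positions.append(int(parts[0]))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return sorted(positions)


# --- JSON -------------------------------------------------------------------

def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
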