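"""Deterministic synthetic pericentromere-like fixture generator.

Builds a repeat-rich reference chromosome plus five deletion mutants whose
junction parameters (breakpoints, filler DNA, microhomology, repetitive vs
unique flanks) are known exactly, so every downstream stage of the pipeline
can be tested against ground truth.

The default fixture is a 6.0 Mbp chromosome carrying

* three dispersed satellite arrays (perfect tandem copies of a 178 bp
  monomer within an array; monomers of different arrays diverged ~10%),
* three (AG)n dinucleotide tracts and one (CT)n tract,
* three diverged transposon-remnant copies ("ATHILA-like"),
* one A/T-rich, MAR-like tract seeded with ATTA motifs,
* unique gene-like background everywhere else (64% A+T),

and the five deletion alleles whose south breakpoints all cluster in an
~80 kbp window (the south breakpoint cluster).  Two alleles (bp-1, bp-2)
break inside repeats on the north side; three (bp-3, bp-5, bp-11) have
unique flanks on both sides.  A 100x scaled-down fixture with the same
qualitative structure is provided for fast tests.

Junction distinctness
---------------------
So that junction mapping is exact rather than probabilistic, the generator
enforces a handful of single-base guards around each planted junction: the
first mismatching base on each side of a junction really mismatches, planted
microhomology terminates, and repetitive flanks remain exactly repetitive up
to the junction (the base following each repeat copy differs from the first
retained south base).  All guards edit deleted or near-junction reference
bases before any mutant or primer is derived, so every product of the
generator is mutually consistent for any seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import count_occurrences, revcomp
from .errors import DataError, FeatureCollisionError
from .genome import AlleleModel, FeatureAnnotation, Genome, PrimerPair, apply_allele
from . import io as bsio

DEFAULT_SEED = 20121
_BASES = "ACGT"
_AT_BIAS = (0.32, 0.18, 0.18, 0.32)  # A, C, G, T -> 64% A+T background


@dataclass(frozen=True)
class FeatureSpec:
    """One entry of a reference feature plan (1-based inclusive interval)."""

    kind: str
    start: int
    end: int
    copy_group: str | None = None
    monomer_len: int = 178
    divergence: float = 0.10  # max pairwise divergence within a copy group

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def annotation(self) -> FeatureAnnotation:
        return FeatureAnnotation(self.kind, self.start, self.end, self.copy_group)


@dataclass(frozen=True)
class ReferencePlan:
    name: str
    length: int
    features: tuple[FeatureSpec, ...] = ()


@dataclass
class Fixture:
    """Everything the pipeline consumes, with its ground truth attached."""

    reference: Genome
    annotations: list[FeatureAnnotation]
    alleles: list[AlleleModel]
    mutants: dict[str, Genome]
    panel: list[PrimerPair]
    decoy: Genome
    seed: int
    scaled: bool

    @property
    def parent_label(self) -> str:
        return self.reference.name

    def allele(self, name: str) -> AlleleModel:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)


# ---------------------------------------------------------------------------
# sequence synthesis primitives
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, p=_AT_BIAS) -> np.ndarray:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=n, p=list(p))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-mutate a uint8 base array; every hit becomes a *different* base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits):
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = alphabet[alphabet != out[i]]
            out[i] = rng.choice(choices)
    return out


def _tile(unit: np.ndarray, length: int) -> np.ndarray:
    reps = length // len(unit) + 1
    return np.tile(unit, reps)[:length]


def build_reference(
    plan: ReferencePlan, seed: int
) -> tuple[Genome, list[FeatureAnnotation]]:
    """Synthesize a reference genome from a feature plan, deterministically.

    Features must not overlap ("feature collision").  Copy groups share a
    common ancestral sequence; each copy is independently mutated at half the
    group divergence so pairwise divergence stays at or below the declared
    maximum while remaining clearly diverged.
    """
    if plan.length < 1:
        raise DataError("genome length must be >= 1")
    feats = sorted(plan.features, key=lambda f: f.start)
    prev_end = 0
    for f in feats:
        if f.start <= prev_end:
            raise FeatureCollisionError(
                f"feature collision at [{f.start}, {f.end}]"
            )
        if f.end > plan.length:
            raise DataError(f"feature [{f.start}, {f.end}] outside genome")
        prev_end = f.end

    rng = np.random.default_rng(seed)
    arr = _random_bases(rng, plan.length)

    # shared ancestral sequences per copy group, drawn in sorted-name order
    ancestors: dict[str, np.ndarray] = {}
    for group in sorted({f.copy_group for f in feats if f.copy_group}):
        members = [f for f in feats if f.copy_group == group]
        if members[0].kind == "satellite":
            ancestors[group] = _random_bases(rng, members[0].monomer_len, p=(0.25,) * 4)
        elif members[0].kind == "transposon_remnant":
            ancestors[group] = _random_bases(rng, members[0].length, p=(0.25,) * 4)

    for f in feats:
        n = f.length
        sl = slice(f.start - 1, f.end)
        if f.kind == "satellite":
            monomer = _mutate(ancestors[f.copy_group], f.divergence / 2, rng)
            arr[sl] = _tile(monomer, n)
        elif f.kind in ("AG_repeat", "CT_repeat"):
            unit = np.frombuffer(f.kind[:2].encode(), dtype=np.uint8)
            arr[sl] = _tile(unit, n)
        elif f.kind == "transposon_remnant":
            arr[sl] = _mutate(ancestors[f.copy_group], f.divergence / 2, rng)
        elif f.kind == "AT_tract":
            tract = _random_bases(rng, n, p=(0.425, 0.075, 0.075, 0.425))
            motif = np.frombuffer(b"ATTA", dtype=np.uint8)
            for off in range(10, n - 4, 120):
                tract[off : off + 4] = motif
            arr[sl] = tract
        elif f.kind == "unique_segment":
            pass  # unique background is already unique; keep the annotation
        else:  # pragma: no cover - FeatureAnnotation already validates kinds
            raise DataError(f"unknown feature kind {f.kind!r}")

    genome = Genome(plan.name, arr.tobytes().decode("ascii"))
    return genome, [f.annotation() for f in feats]


# ---------------------------------------------------------------------------
# junction planting
# ---------------------------------------------------------------------------

def _set_base_differing(arr: bytearray, idx0: int, *avoid: int) -> None:
    """Set arr[idx0] to the first of ACGT not in ``avoid`` (byte values)."""
    for b in b"ACGT":
        if b not in avoid:
            arr[idx0] = b
            return


def plant_junction(arr: bytearray, allele: AlleleModel) -> None:
    """Edit reference bases so the allele's junction is exact and unambiguous.

    For unique-flank alleles: plants ``microhomology_len`` bases (deleted
    north start := retained south start), then guards that the homology
    terminates and that the junction cannot shift or blend into filler.
    All guard edits touch deleted bases where possible; the single exception
    (filler + microhomology) may adjust the first retained south bases before
    re-copying the homology.
    """
    nb, sb, m = allele.north_bp, allele.south_bp, allele.microhomology_len
    filler = allele.filler
    if m > 0:
        if filler:
            # filler must not blend into the (copied) south start
            if arr[sb - 1] == ord(filler[0]):
                _set_base_differing(arr, sb - 1, ord(filler[0]))
        arr[nb : nb + m] = arr[sb - 1 : sb - 1 + m]  # deleted north start := south start
        # homology terminates after exactly m bases
        if arr[nb + m] == arr[sb - 1 + m]:
            _set_base_differing(arr, nb + m, arr[sb - 1 + m])
        if not filler and arr[nb - 1] == arr[sb - 2]:
            # blunt + microhomology: planted coordinates are already the
            # left-most equivalent placement, so block a further left shift
            _set_base_differing(arr, sb - 2, arr[nb - 1])
    if filler:
        # prefix anchor must stop at the junction, and with no planted
        # homology the donor junctions must share no first base either
        if m == 0 and (arr[nb] == ord(filler[0]) or arr[nb] == arr[sb - 1]):
            _set_base_differing(arr, nb, ord(filler[0]), arr[sb - 1])
        # ...and the suffix anchor must not absorb the filler tail
        if arr[sb - 2] == ord(filler[-1]):
            _set_base_differing(arr, sb - 2, ord(filler[-1]))
    elif m == 0:
        # blunt junction: no equivalent left or right placement
        if arr[nb] == arr[sb - 1]:
            _set_base_differing(arr, nb, arr[sb - 1])
        if arr[nb - 1] == arr[sb - 2]:
            _set_base_differing(arr, sb - 2, arr[nb - 1])


def _guard_repetitive_junction(
    arr: bytearray, allele: AlleleModel, copies: list[FeatureAnnotation]
) -> None:
    """Keep a repeat-flank junction genuinely ambiguous.

    The first retained south base must differ from the repeat's continuation
    base (so every in-repeat placement of the junction read's prefix stops at
    the same length), and the base after each dispersed repeat copy must
    differ from that south base (so no end-of-copy placement out-extends the
    others and becomes spuriously unique).
    """
    nb, sb = allele.north_bp, allele.south_bp
    cont = arr[nb]  # continuation base inside the repeat (period-shifted too)
    if arr[sb - 1] == cont:
        _set_base_differing(arr, sb - 1, cont)
    if arr[sb - 2] == arr[nb - 1]:  # no leftward suffix extension
        _set_base_differing(arr, sb - 2, arr[nb - 1])
    for c in copies:
        if c.end < len(arr) and arr[c.end] == arr[sb - 1]:
            _set_base_differing(arr, c.end, arr[sb - 1], cont)


# ---------------------------------------------------------------------------
# the shipped fixtures
# ---------------------------------------------------------------------------

FILLER_19 = "TCCATGTAGTAAGGTAATT"


def default_reference_plan() -> ReferencePlan:
    """6.0 Mbp pericentromere-like plan (coordinates in bp)."""
    feats = [
        FeatureSpec("satellite", 120_001, 130_000, "CEN180-like"),
        FeatureSpec("AG_repeat", 700_001, 700_400),
        FeatureSpec("transposon_remnant", 1_500_001, 1_504_000, "ATHILA-like"),
        FeatureSpec("AG_repeat", 2_200_001, 2_200_800),
        FeatureSpec("satellite", 3_900_001, 3_910_000, "CEN180-like"),
        FeatureSpec("unique_segment", 4_286_500, 4_287_500),  # bp-11 north flank
        FeatureSpec("satellite", 4_305_001, 4_315_000, "CEN180-like"),
        FeatureSpec("transposon_remnant", 4_420_001, 4_424_000, "ATHILA-like"),
        FeatureSpec("transposon_remnant", 4_600_001, 4_604_000, "ATHILA-like"),
        FeatureSpec("AG_repeat", 4_748_001, 4_750_600),  # bp-1 north flank
        FeatureSpec("unique_segment", 4_860_500, 4_861_500),  # bp-3 north flank
        FeatureSpec("unique_segment", 5_101_500, 5_102_500),  # bp-5 north flank
        FeatureSpec("unique_segment", 5_151_001, 5_153_000),  # gene-like unique body
        FeatureSpec("unique_segment", 5_164_200, 5_165_200),  # bp-2 south flank
        FeatureSpec("AT_tract", 5_175_001, 5_176_200),  # MAR-like tract in the SBC
        FeatureSpec("unique_segment", 5_202_500, 5_203_500),  # bp-1 south flank
        FeatureSpec("unique_segment", 5_211_600, 5_212_600),  # bp-11 south flank
        FeatureSpec("CT_repeat", 5_230_001, 5_230_500),
        FeatureSpec("unique_segment", 5_242_500, 5_243_500),  # bp-5 south flank
        FeatureSpec("unique_segment", 5_247_100, 5_248_100),  # bp-3 south flank
    ]
    return ReferencePlan("chr4-like", 6_000_000, tuple(feats))


def default_alleles() -> list[AlleleModel]:
    """The five deletion allele models (sizes are exact ground truth)."""
    return [
        AlleleModel("bp-1", 4_750_000, 5_203_000, "", "repetitive", 0, "EMS"),
        AlleleModel("bp-2", 4_310_000, 5_164_664, "", "repetitive", 0, "fast neutrons"),
        AlleleModel("bp-3", 4_861_000, 5_247_635, "G", "unique", 0, "fast neutrons"),
        AlleleModel("bp-5", 5_102_000, 5_242_997, FILLER_19, "unique", 3, "T-DNA"),
        AlleleModel("bp-11", 4_287_000, 5_212_159, "", "unique", 0, "x-rays"),
    ]


def scaled_reference_plan() -> ReferencePlan:
    """60 kbp fast-test plan with the same qualitative structure."""
    feats = [
        FeatureSpec("satellite", 1_201, 2_200, "CEN180-like", monomer_len=30),
        FeatureSpec("AG_repeat", 7_001, 7_200),
        FeatureSpec("transposon_remnant", 15_001, 16_000, "ATHILA-like"),
        FeatureSpec("AG_repeat", 22_001, 22_400),
        FeatureSpec("satellite", 39_001, 40_000, "CEN180-like", monomer_len=30),
        FeatureSpec("unique_segment", 42_500, 42_900, "bp-11s north flank"),
        FeatureSpec("satellite", 42_951, 43_950, "CEN180-like", monomer_len=30),
        FeatureSpec("transposon_remnant", 44_201, 45_200, "ATHILA-like"),
        FeatureSpec("transposon_remnant", 46_001, 47_000, "ATHILA-like"),
        FeatureSpec("AG_repeat", 47_241, 47_890),
        FeatureSpec("unique_segment", 48_150, 48_550),
        FeatureSpec("unique_segment", 50_550, 50_950),
        FeatureSpec("unique_segment", 51_330, 51_730),
        FeatureSpec("AT_tract", 51_751, 52_050),
        FeatureSpec("CT_repeat", 52_301, 52_420),
        FeatureSpec("unique_segment", 52_550, 52_950),
    ]
    return ReferencePlan("chr4s-like", 60_000, tuple(feats))


def scaled_alleles() -> list[AlleleModel]:
    return [
        AlleleModel("bp-1", 47_550, 51_950, "", "repetitive", 0, "EMS"),
        AlleleModel("bp-2", 43_450, 51_530, "", "repetitive", 0, "fast neutrons"),
        AlleleModel("bp-3", 48_350, 52_350, "G", "unique", 0, "fast neutrons"),
        AlleleModel("bp-5", 50_750, 52_750, FILLER_19, "unique", 3, "T-DNA"),
        AlleleModel("bp-11", 42_750, 51_150, "", "unique", 0, "x-rays"),
    ]


@dataclass(frozen=True)
class PanelDesign:
    region_start: int
    region_end: int
    step: int
    amplicon: int
    primer_len: int = 20
    n_decoys: int = 2


DEFAULT_PANEL = PanelDesign(4_200_000, 5_400_000, 40_000, 900)
SCALED_PANEL = PanelDesign(42_000, 54_000, 400, 300)


def design_panel(
    reference: Genome,
    design: PanelDesign,
    rng: np.random.Generator,
    avoid_in: list[Genome] = (),
) -> list[PrimerPair]:
    """Tile the scan region with uniquely-binding primer pairs.

    A tile is skipped when either primer (or its reverse complement) binds
    the reference more than once, or binds the opposite strand at all; this
    drops tiles that fall in repeats.  ``n_decoys`` extra pairs of random
    primers absent from the reference *and* every genome in ``avoid_in``
    emulate parent-polymorphic, uninformative loci.
    """
    seq = reference.sequence
    plen = design.primer_len
    panel: list[PrimerPair] = []
    for s in range(design.region_start, design.region_end + 1, design.step):
        e = s + design.amplicon - 1
        if e > len(seq):
            break
        fwd = reference.sub(s, s + plen - 1)
        rev = revcomp(reference.sub(e - plen + 1, e))
        ok = (
            count_occurrences(seq, fwd, limit=2) == 1
            and count_occurrences(seq, revcomp(rev), limit=2) == 1
            and count_occurrences(seq, revcomp(fwd), limit=1) == 0
            and count_occurrences(seq, rev, limit=1) == 0
        )
        if ok:
            panel.append(PrimerPair(f"p{s}", fwd, rev, s, e))
    genomes = [reference, *avoid_in]
    made = 0
    while made < design.n_decoys:
        cand = "".join(rng.choice(list(_BASES), size=plen))
        fwd, rev = cand, revcomp("".join(rng.choice(list(_BASES), size=plen)))
        absent = all(
            count_occurrences(g.sequence, p, limit=1) == 0
            for g in genomes
            for p in (fwd, revcomp(fwd), rev, revcomp(rev))
        )
        if absent:
            made += 1
            panel.append(PrimerPair(f"decoy{made}", fwd, rev))
    return panel


def _make_decoy(rng: np.random.Generator, length: int = 40_000) -> Genome:
    """A 'chromosome 3'-like decoy carrying a 1-mismatch copy of the filler."""
    arr = bytearray(_random_bases(rng, length).tobytes())
    pos0 = 20_010  # 0-based insertion offset
    near = bytearray(FILLER_19.encode())
    old = near[9]
    _set_base_differing(near, 9, old)
    arr[pos0 : pos0 + len(near)] = near
    g = Genome("chr3-like", arr.decode("ascii"))
    # the decoy must not contain a perfect filler copy by chance
    assert FILLER_19 not in g.sequence and revcomp(FILLER_19) not in g.sequence
    return g


def make_fixture(seed: int = DEFAULT_SEED, scaled: bool = False) -> Fixture:
    """Build the complete shipped fixture (reference, mutants, panel, decoy)."""
    plan = scaled_reference_plan() if scaled else default_reference_plan()
    alleles = scaled_alleles() if scaled else default_alleles()
    reference, annotations = build_reference(plan, seed)
    arr = bytearray(reference.sequence.encode("ascii"))

    by_group: dict[str | None, list[FeatureAnnotation]] = {}
    for a in annotations:
        by_group.setdefault(a.copy_group, []).append(a)
    sat_copies = by_group.get("CEN180-like", [])
    ag_copies = [a for a in annotations if a.kind == "AG_repeat"]

    for allele in alleles:
        if allele.north_flank_class == "repetitive":
            inside_sat = any(
                c.start <= allele.north_bp <= c.end for c in sat_copies
            )
            _guard_repetitive_junction(
                arr, allele, sat_copies if inside_sat else ag_copies
            )
        else:
            plant_junction(arr, allele)

    # a chance perfect filler copy in the reference would confound phase 6
    seq = arr.decode("ascii")
    for probe in (FILLER_19, revcomp(FILLER_19)):
        hit = seq.find(probe)
        if hit != -1:  # pragma: no cover - ~2e-5 per seed
            _set_base_differing(arr, hit + 9, arr[hit + 9])
            seq = arr.decode("ascii")

    reference = Genome(plan.name, seq)
    mutants = {
        a.name: apply_allele(reference, a, name=a.name) for a in alleles
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    panel = design_panel(
        reference,
        SCALED_PANEL if scaled else DEFAULT_PANEL,
        rng,
        avoid_in=list(mutants.values()),
    )
    decoy = _make_decoy(rng, length=4_000 if scaled else 40_000)
    return Fixture(
        reference=reference,
        annotations=annotations,
        alleles=alleles,
        mutants=mutants,
        panel=panel,
        decoy=decoy,
        seed=seed,
        scaled=scaled,
    )


def write_fixture_set(
    outdir: str | Path, seed: int = DEFAULT_SEED, scaled: bool = False
) -> Fixture:
    """Write the fixture to disk: 7 FASTA files + allele/panel/feature tables.

    Re-running with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = make_fixture(seed=seed, scaled=scaled)
    bsio.write_fasta(outdir / "reference.fasta", [fx.reference])
    for name, g in sorted(fx.mutants.items()):
        bsio.write_fasta(outdir / f"{name}.fasta", [g])
    bsio.write_fasta(outdir / "decoy.fasta", [fx.decoy])
    bsio.write_alleles_tsv(outdir / "alleles.tsv", fx.alleles)
    bsio.write_panel_tsv(outdir / "panel.tsv", fx.panel)
    bsio.write_bed(
        outdir / "features.bed",
        [
            (fx.reference.name, a.start, a.end, a.copy_group or a.kind)
            for a in fx.annotations
        ],
    )
    return fx


# ---------------------------------------------------------------------------
# random alleles for property testing
# ---------------------------------------------------------------------------

def random_allele_genome(
    rng: np.random.Generator,
    genome_len: int = 30_000,
    max_filler: int = 25,
    max_microhomology: int = 5,
) -> tuple[Genome, AlleleModel, Genome]:
    """Draw a random unique-flank allele on a random genome.

    Returns (reference, allele, mutant) with the junction planted exactly as
    :func:`plant_junction` prescribes, for round-trip recovery tests.
    """
    arr = bytearray(_random_bases(rng, genome_len).tobytes())
    min_del = 200
    nb = int(rng.integers(2_000, genome_len - 2_000 - min_del))
    sb = int(rng.integers(nb + 1 + min_del, genome_len - 1_900))
    m = int(rng.integers(0, max_microhomology + 1))
    fl = int(rng.integers(0, max_filler + 1))
    filler = "".join(rng.choice(list(_BASES), size=fl)) if fl else ""
    if fl == 0 and m > 0 and sb - nb - 1 <= m + 1:
        m = 0
    allele = AlleleModel("rand", nb, sb, filler, "unique", m, "synthetic")
    plant_junction(arr, allele)
    reference = Genome("rand-ref", arr.decode("ascii"))
    mutant = apply_allele(reference, allele, name="rand-mut")
    return reference, allele, mutant
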