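"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own scanning strategies: direct
counting, exhaustive enumeration and naive string comparison only.
"""

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def naive_at_fraction(window_seq: str) -> float:
    return (window_seq.count("A") + window_seq.count("T")) / len(window_seq)


def naive_tandem_spans(seq: str, max_unit: int = 6, min_copies: int = 4) -> set:
    """Every maximal primitive tandem array, phase-rotations collapsed."""
    per_unit: dict[int, list[tuple[int, int, str]]] = {}
    for u in range(1, max_unit + 1):
        for i in range(len(seq)):
            unit = seq[i : i + u]
            if len(unit) < u or "N" in unit:
                continue
            c = 1
            while seq[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            if c >= min_copies:
                if any(
                    u % d == 0 and unit == unit[:d] * (u // d) for d in range(1, u)
                ):
                    continue  # non-primitive unit
                canon = min(unit[k:] + unit[:k] for k in range(u))
                per_unit.setdefault(u, []).append((i + 1, i + c * u, canon))
    spans = set()
    for u, reports in per_unit.items():
        kept: list[tuple[int, int, str]] = []
        for s, e, canon in sorted(reports):
            if any(s <= e0 and canon == c0 for _s0, e0, c0 in kept):
                continue  # phase rotation of an already-kept run
            kept.append((s, e, canon))
        spans.update((s, e) for s, e, _ in kept)
    return spans


def naive_inverted(seq: str, min_stem: int = 8, max_loop: int = 6) -> set:
    """(left-arm start, loop, stem) of every maximal hairpin candidate."""
    found = set()
    n = len(seq)
    for i in range(n):
        for loop in range(0, max_loop + 1):
            j = i + 1 + loop
            if j >= n:
                break
            k = 0
            while i - k >= 0 and j + k < n and _COMP.get(seq[i - k]) == seq[j + k]:
                k += 1
            if k >= min_stem:
                if loop >= 2 and _COMP.get(seq[i + 1]) == seq[i + loop]:
                    continue  # same stem with a narrower loop exists
                found.add((i - k + 2, loop, k))
    return found


def naive_mar_window(win: str) -> tuple[float, int]:
    at = (win.count("A") + win.count("T")) / len(win)
    count = 0
    for motif in ("ATTA", "TAAT", "ATTTA", "TAAAT"):
        count += sum(1 for k in range(len(win)) if win.startswith(motif, k))
    return at, count


def brute_force_bounds(parent_cells, allele_cells, coords, genome_length):
    """Interval-inference oracle: direct scan over informative amplicons."""
    informative = [
        (s, e, a)
        for pc, a, (s, e) in zip(parent_cells, allele_cells, coords)
        if pc == "p"
    ]
    absent = [(s, e) for s, e, a in informative if a == "a"]
    present = [(s, e) for s, e, a in informative if a != "a"]
    if not absent:
        return None, None
    inner = (min(s for s, _ in absent), max(e for _, e in absent))
    norths = [e for s, e in present if e < inner[0]]
    souths = [s for s, _ in present if s > inner[1]]
    outer = (
        max(norths) if norths else 0,
        min(souths) if souths else genome_length + 1,
    )
    return inner, outer


def leftmost_blunt_placement(read: str, ref_seq: str, anchor: int = 15):
    """Junction-mapping oracle for blunt deletions on unique flanks.

    Anchors the read's outermost bases at their unique reference positions,
    then enumerates every split of the read between the anchors, keeping
    splits whose prefix and suffix both match the reference; the left-most
    valid split is the expected call.
    """
    n = len(read)
    a0 = ref_seq.find(read[:anchor])
    assert a0 != -1 and ref_seq.find(read[:anchor], a0 + 1) == -1
    tail = read[-anchor:]
    b_end = ref_seq.find(tail)
    assert b_end != -1 and ref_seq.find(tail, b_end + 1) == -1
    suffix_end = b_end + anchor
    best = None
    for i in range(anchor, n - anchor + 1):
        nb = a0 + i
        sb0 = suffix_end - (n - i)
        if ref_seq[a0:nb] != read[:i] or ref_seq[sb0:suffix_end] != read[i:]:
            continue
        if sb0 + 1 - nb - 1 >= 1 and (best is None or nb < best[0]):
            best = (nb, sb0 + 1, "")
    return best
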