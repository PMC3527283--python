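"""Phase-6 sequence feature scanners for junction/fragile-site characterization.

Four scanners: sliding-window A/T content, perfect tandem repeats, inverted
repeats (hairpin geometry), and a simple matrix-attachment-region (MAR)
propensity rule.  All are perfect-match scanners: thermodynamic folding and
library-based repeat masking are deliberately out of scope, replaced by the
geometric primitives that the junction analyses actually need.  N bases
break repeats and stems and count as neither A/T nor G/C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .errors import DataError

MAR_MOTIFS = ("ATTA", "ATTTA")


@dataclass(frozen=True)
class WindowStat:
    start: int  # 1-based window start
    width: int
    at_fraction: float
    flagged: bool


@dataclass(frozen=True)
class RepeatAnnotation:
    unit: str  # lexicographically smallest rotation of the repeat unit
    copies: int
    start: int
    end: int  # end - start + 1 == copies * len(unit)


@dataclass(frozen=True)
class HairpinCandidate:
    stem_len: int
    loop_len: int
    start: int  # 1-based start of the left arm
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]


@dataclass(frozen=True)
class MarScore:
    start: int
    width: int
    at_fraction: float
    motif_count: int
    candidate: bool


def at_content_windows(
    seq: str, window: int = 50, threshold: float = 0.75, step: int = 1
) -> list[WindowStat]:
    """Per-window A/T fraction with a flag at ``threshold``.

    The defaults (window 50, threshold 0.75) are the standard display used
    for A/T-rich fragile-site plots.
    """
    if window < 1:
        raise DataError("window must be >= 1")
    if len(seq) < window:
        raise DataError("sequence shorter than the window")
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    cum = np.concatenate(([0], np.cumsum(is_at)))
    out = []
    for start0 in range(0, len(seq) - window + 1, step):
        frac = float(cum[start0 + window] - cum[start0]) / window
        out.append(WindowStat(start0 + 1, window, frac, frac >= threshold))
    return out


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def find_tandem_repeats(
    seq: str, max_unit: int = 6, min_copies: int = 4
) -> list[RepeatAnnotation]:
    """Maximal perfect tandem arrays for unit lengths 1..max_unit.

    Only primitive units are reported (an (AC)n array is not re-reported as
    an (ACAC)n array), and units are canonicalized to their lexicographically
    smallest rotation.  A trailing partial unit is not included in the
    reported span, so span length is always copies * unit length.
    """
    seq = seq.upper()
    n = len(seq)
    out: list[RepeatAnnotation] = []
    seen: set[tuple[int, int]] = set()
    for u in range(1, max_unit + 1):
        i = 0
        while i + u <= n:
            unit = seq[i : i + u]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            copies = (j - i) // u
            if copies >= min_copies:
                span = (i + 1, i + copies * u)
                if span not in seen:
                    seen.add(span)
                    out.append(
                        RepeatAnnotation(_canonical_rotation(unit), copies, *span)
                    )
                i = j - u + 1
            else:
                i += 1
    out.sort(key=lambda r: (r.start, r.end))
    return out


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def find_inverted_repeats(
    seq: str, min_stem: int = 10, max_loop: int = 20
) -> list[HairpinCandidate]:
    """Maximal inverted repeats whose arms could base-pair into a hairpin.

    For every center (left-arm end, loop length) the stem is extended as far
    as the sequences stay complementary; a candidate is reported when the
    stem reaches ``min_stem`` and its loop cannot itself pair inward (so a
    hairpin is not re-reported with a wider loop).  Sorted by stem length,
    longest first.
    """
    seq = seq.upper()
    n = len(seq)
    out: list[HairpinCandidate] = []
    for loop in range(0, max_loop + 1):
        for i in range(n):  # i = 0-based left-arm end
            j0 = i + 1 + loop
            if j0 >= n:
                break
            # skip non-maximal loops: the innermost loop positions would pair
            if loop >= 2 and _PAIR.get(seq[i + 1]) == seq[i + loop]:
                continue
            k = 0
            while (
                i - k >= 0
                and j0 + k < n
                and _PAIR.get(seq[i - k]) == seq[j0 + k]
            ):
                k += 1
            if k >= min_stem:
                out.append(
                    HairpinCandidate(
                        stem_len=k,
                        loop_len=loop,
                        start=i - k + 2,
                        left_arm=(i - k + 2, i + 1),
                        right_arm=(j0 + 1, j0 + k),
                    )
                )
    out.sort(key=lambda h: (-h.stem_len, h.start, h.loop_len))
    return out


def mar_propensity(
    seq: str,
    window: int = 300,
    at_min: float = 0.70,
    motifs: tuple[str, ...] = MAR_MOTIFS,
    motif_min: int = 2,
    step: int = 50,
) -> list[MarScore]:
    """Rule-based MAR propensity: A/T-rich windows carrying A/T-patch motifs.

    A window is a candidate when its A/T fraction reaches ``at_min`` and it
    carries at least ``motif_min`` occurrences of the motifs on either
    strand.  This is a deliberately simple stand-in for dedicated MAR
    prediction software; the thresholds are declared constants, not fitted.
    """
    if len(seq) < window:
        raise DataError("sequence shorter than the window")
    seq = seq.upper()
    probes = sorted({m.upper() for m in motifs} | {revcomp(m.upper()) for m in motifs})
    out = []
    for start0 in range(0, len(seq) - window + 1, step):
        win = seq[start0 : start0 + window]
        at = (win.count("A") + win.count("T")) / window
        count = 0
        for p in probes:
            i = win.find(p)
            while i != -1:
                count += 1
                i = win.find(p, i + 1)
        out.append(
            MarScore(
                start0 + 1, window, at, count,
                candidate=(at >= at_min and count >= motif_min),
            )
        )
    return out


def merge_candidate_regions(scores: list[MarScore]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent candidate windows into reporting intervals."""
    regions: list[list[int]] = []
    for s in sorted(scores, key=lambda s: s.start):
        if not s.candidate:
            continue
        end = s.start + s.width - 1
        if regions and s.start <= regions[-1][1] + 1:
            regions[-1][1] = max(regions[-1][1], end)
        else:
            regions.append([s.start, end])
    return [tuple(r) for r in regions]
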