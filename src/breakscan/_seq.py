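"""Low-level sequence utilities shared across modules.

All public modules use 1-based inclusive coordinates; helpers here that take
0-based offsets say so explicitly.
"""

from __future__ import annotations

import re

from .errors import DataError

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = re.compile(r"[ACGTN]+\Z")
_VALID_ACGT = re.compile(r"[ACGT]+\Z")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def check_alphabet(seq: str, allow_n: bool = True, what: str = "sequence") -> None:
    pattern = _VALID if allow_n else _VALID_ACGT
    if seq and not pattern.match(seq):
        raise DataError(f"{what} contains characters outside the DNA alphabet")
    if not seq and what != "filler":
        raise DataError(f"{what} is empty")


def find_all(haystack: str, needle: str, limit: int | None = None) -> list[int]:
    """All (possibly overlapping) 0-based occurrence starts of ``needle``.

    ``limit`` stops the scan early once that many hits were found; useful for
    uniqueness tests where only 0/1/many matters.
    """
    if not needle:
        raise DataError("empty search pattern")
    hits: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        if limit is not None and len(hits) >= limit:
            break
        i = haystack.find(needle, i + 1)
    return hits


def count_occurrences(haystack: str, needle: str, limit: int | None = None) -> int:
    return len(find_all(haystack, needle, limit=limit))


def longest_prefix_in(haystack: str, seq: str) -> int:
    """Length of the longest prefix of ``seq`` occurring anywhere in ``haystack``.

    "prefix of length L occurs" is monotone in L, so a binary search over the
    prefix length needs only O(log |seq|) substring scans.
    """
    if not seq or haystack.find(seq[0]) == -1:
        return 0
    lo, hi = 1, len(seq)  # invariant: prefix of length lo occurs
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if haystack.find(seq[:mid]) != -1:
            lo = mid
        else:
            hi = mid - 1
    return lo


def longest_suffix_in(haystack: str, seq: str) -> int:
    """Length of the longest suffix of ``seq`` occurring anywhere in ``haystack``."""
    if not seq or haystack.find(seq[-1]) == -1:
        return 0
    lo, hi = 1, len(seq)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if haystack.find(seq[-mid:]) != -1:
            lo = mid
        else:
            hi = mid - 1
    return lo


def identity(a: str, b: str) -> float:
    """Per-base identity of two equal-length sequences."""
    if len(a) != len(b):
        raise DataError("identity requires equal-length sequences")
    if not a:
        raise DataError("identity of empty sequences is undefined")
    return sum(x == y for x, y in zip(a, b)) / len(a)
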