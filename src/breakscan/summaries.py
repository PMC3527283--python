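"""Small region statistics over external tracks.

Two statistics: the chromatin-fraction normalization used for per-region
pie charts of immunoprecipitation enrichments, and interorigin distance
summaries for replication-origin coordinate lists (fragile sites sit in
origin-poor regions, so the gap containing a region of interest is compared
against the chromosome-wide gap distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


def chromatin_fractions(
    marks: list[tuple[str, float]], clamp_negative: bool = True
) -> tuple[dict[str, float], str]:
    """Normalize per-mark IP/input log ratios to fractions of their sum.

    fraction_i = ratio_i / sum(ratios).  Negative ratios (depletion) are
    clamped to 0 first by default so that fractions are non-negative; with
    ``clamp_negative=False`` raw values are summed.  Returns (fractions,
    note); when nothing is positive after clamping all fractions are 0 and
    the note says "no enrichment".
    """
    if not marks:
        raise DataError("empty mark list")
    names = [n for n, _ in marks]
    values = np.array([v for _, v in marks], dtype=float)
    if clamp_negative:
        values = np.clip(values, 0.0, None)
    total = values.sum()
    if total == 0:
        return {n: 0.0 for n in names}, "no enrichment"
    return dict(zip(names, (values / total).tolist())), ""


@dataclass(frozen=True)
class InterOriginStats:
    median_gap: float
    mean_gap: float
    gaps: tuple[int, ...]


def interorigin_stats(origins: list[int]) -> InterOriginStats:
    """Median and mean of successive origin-to-origin distances.

    Origins must be strictly increasing; the median uses the midpoint
    convention for an even number of gaps.
    """
    if len(origins) < 2:
        raise DataError("need at least 2 origins for gap statistics")
    arr = np.asarray(origins)
    if not np.all(np.diff(arr) > 0):
        raise DataError("origin positions must be strictly increasing")
    gaps = np.diff(arr)
    return InterOriginStats(
        float(np.median(gaps)), float(np.mean(gaps)), tuple(int(g) for g in gaps)
    )


def containing_gap(
    origins: list[int], interval: tuple[int, int]
) -> tuple[tuple[int, int], int]:
    """The origin pair bracketing an interval, and the size of that gap.

    The interval must lie strictly between two successive origins; an
    interval containing an origin has no unique bracketing gap.
    """
    start, end = interval
    if start > end:
        raise DataError(f"bad interval [{start}, {end}]")
    arr = sorted(origins)
    if len(arr) < 2 or start <= arr[0] or end >= arr[-1]:
        if not (arr and arr[0] < start and end < arr[-1]):
            raise DataError("interval does not lie between the outermost origins")
    if any(start <= o <= end for o in arr):
        raise DataError("interval spans an origin")
    lo = max(o for o in arr if o < start)
    hi = min(o for o in arr if o > end)
    return (lo, hi), hi - lo
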