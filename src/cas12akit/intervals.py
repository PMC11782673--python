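"""Static interval index with O(log n + k) overlap queries.

Built once from a list of half-open intervals; supports point and range
overlap queries.  Uses the classic sorted-starts + running-max-end layout,
so no third-party interval-tree dependency is needed.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterable, Sequence


class IntervalIndex:
    """Immutable index over 0-based half-open intervals ``(start, end, *payload)``."""

    def __init__(self, intervals: Iterable[Sequence]):
        ivs = sorted(intervals, key=lambda iv: (iv[0], iv[1]))
        self._ivs = ivs
        self._starts = [iv[0] for iv in ivs]
        maxend = []
        running = float("-inf")
        for iv in ivs:
            running = max(running, iv[1])
            maxend.append(running)
        self._maxend = maxend

    def __len__(self) -> int:
        return len(self._ivs)

    def overlaps(self, start: int, end: int) -> bool:
        """True if any stored interval intersects [start, end)."""
        for _ in self.query(start, end):
            return True
        return False

    def overlaps_point(self, pos: int) -> bool:
        return self.overlaps(pos, pos + 1)

    def query(self, start: int, end: int):
        """Yield stored intervals intersecting the half-open range [start, end)."""
        if start >= end or not self._ivs:
            return
        # candidates: all intervals with start < end, scanned right-to-left
        # until the running max end falls below the query start.
        hi = bisect_left(self._starts, end)
        for i in range(hi - 1, -1, -1):
            if self._maxend[i] <= start:
                break
            iv = self._ivs[i]
            if iv[1] > start:
                yield iv

    def query_point(self, pos: int):
        yield from self.query(pos, pos + 1)


def linear_scan_overlaps(intervals, start: int, end: int):
    """Brute-force overlap scan; the reference oracle for IntervalIndex."""
    return [iv for iv in intervals if iv[0] < end and iv[1] > start]
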