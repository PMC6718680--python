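"""Half-open time-interval sets and the algebra the detectors rely on.

All event classes (alpha-suppressions, iso-electric suppressions, their
complements) are represented as sorted, pairwise-disjoint, half-open
``[start, end)`` intervals in seconds from the start of the recording.
"""
from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np

__all__ = ["IntervalSet"]


class IntervalSet:
    """A sorted, pairwise-disjoint collection of half-open time intervals.

    Parameters
    ----------
    pairs
        Iterable of ``(start_s, end_s)`` pairs. Must already be sorted by
        start and pairwise disjoint unless constructed via :meth:`coalesce`.
    validate
        If true (default) the invariants are checked and a ``ValueError``
        is raised on violation.
    """

    __slots__ = ("_starts", "_ends")

    def __init__(self, pairs: Iterable[tuple[float, float]] = (), *, validate: bool = True):
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            self._starts = np.empty(0)
            self._ends = np.empty(0)
            return
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected a sequence of (start, end) pairs")
        self._starts = arr[:, 0].copy()
        self._ends = arr[:, 1].copy()
        if validate:
            if not np.all(self._ends > self._starts):
                raise ValueError("every interval must satisfy end > start")
            if not np.all(np.diff(self._starts) >= 0):
                raise ValueError("intervals must be sorted by start")
            if np.any(self._starts[1:] < self._ends[:-1]):
                raise ValueError("intervals must be pairwise disjoint")

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def coalesce(cls, pairs: Iterable[tuple[float, float]]) -> "IntervalSet":
        """Build from arbitrary pairs, sorting and merging overlapping or
        touching intervals; empty (end <= start) pairs are dropped."""
        arr = [(s, e) for s, e in pairs if e > s]
        if not arr:
            return cls()
        arr.sort()
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return cls(merged, validate=False)

    @classmethod
    def from_mask(cls, mask: np.ndarray, fs: float, t0: float = 0.0) -> "IntervalSet":
        """Convert a boolean sample mask at rate ``fs`` into intervals."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0 or not mask.any():
            return cls()
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        return cls(np.column_stack([starts, ends]) / fs + t0, validate=False)

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    @property
    def starts(self) -> np.ndarray:
        return self._starts

    @property
    def ends(self) -> np.ndarray:
        return self._ends

    @property
    def durations(self) -> np.ndarray:
        return self._ends - self._starts

    def __len__(self) -> int:
        return self._starts.size

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self._starts.tolist(), self._ends.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.allclose(self._starts, other._starts)
            and np.allclose(self._ends, other._ends)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({list(self)!r})"

    def total_duration(self) -> float:
        return float(np.sum(self.durations))

    # ------------------------------------------------------------------ #
    # set algebra
    # ------------------------------------------------------------------ #
    def overlap(self, a: float, b: float) -> float:
        """Covered duration inside the window ``[a, b)``."""
        if b <= a or len(self) == 0:
            return 0.0
        lo = np.minimum(np.maximum(self._starts, a), b)
        hi = np.minimum(np.maximum(self._ends, a), b)
        return float(np.sum(hi - lo))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.coalesce(list(self) + list(other))

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        i = j = 0
        while i < len(self) and j < len(other):
            s = max(self._starts[i], other._starts[j])
            e = min(self._ends[i], other._ends[j])
            if e > s:
                out.append((s, e))
            if self._ends[i] < other._ends[j]:
                i += 1
            else:
                j += 1
        return IntervalSet(out, validate=False)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        """Portions of this set not covered by ``other``."""
        out = []
        j = 0
        o_starts, o_ends = other._starts, other._ends
        for s, e in self:
            cur = s
            while j < len(o_starts) and o_ends[j] <= cur:
                j += 1
            k = j
            while k < len(o_starts) and o_starts[k] < e:
                if o_starts[k] > cur:
                    out.append((cur, o_starts[k]))
                cur = max(cur, o_ends[k])
                if cur >= e:
                    break
                k += 1
            if cur < e:
                out.append((cur, e))
        return IntervalSet([p for p in out if p[1] > p[0]], validate=False)

    def complement(self, span: tuple[float, float]) -> "IntervalSet":
        return IntervalSet([span], validate=False).difference(self)

    def clipped(self, a: float, b: float) -> "IntervalSet":
        return self.intersection(IntervalSet([(a, b)], validate=False))

    # ------------------------------------------------------------------ #
    # morphology (per-endpoint convention)
    # ------------------------------------------------------------------ #
    def dilated(self, by: float) -> "IntervalSet":
        """Extend each endpoint outward by ``by`` seconds, merging overlaps."""
        if by < 0:
            raise ValueError("dilation must be >= 0")
        return IntervalSet.coalesce(
            (s - by, e + by) for s, e in self
        )

    def eroded(self, by: float) -> "IntervalSet":
        """Pull each endpoint inward by ``by`` seconds; empty results drop."""
        if by < 0:
            raise ValueError("erosion must be >= 0")
        return IntervalSet(
            [(s + by, e - by) for s, e in self if (e - by) > (s + by)],
            validate=False,
        )

    def to_mask(self, fs: float, n: int) -> np.ndarray:
        """Rasterize onto an ``n``-sample boolean grid at rate ``fs``."""
        mask = np.zeros(n, dtype=bool)
        for s, e in self:
            i = max(int(np.ceil(s * fs - 1e-9)), 0)
            j = min(int(np.ceil(e * fs - 1e-9)), n)
            if j > i:
                mask[i:j] = True
        return mask
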