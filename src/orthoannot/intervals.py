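"""Genomic interval arithmetic on half-open, 0-based coordinates.

Every region handled by this package — exons, regulatory features, TAD
boundaries, alignment blocks — is reduced to a :class:`GenomicInterval`
(chromosome, start, end) with ``start < end``, 0-based and half-open.
:class:`IntervalSet` holds a normalized (sorted, merged, disjoint) collection
of such intervals per chromosome and supports the set algebra the
conservation statistics are built from: union, intersection, difference,
complement, and vectorized overlap-length queries.

Coordinates are normalized at the I/O boundary: GTF/GFF input (1-based,
inclusive) is converted on read, chain files are already 0-based half-open.
Chromosome names are stored without a ``chr`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "normalize_chrom",
    "read_bed",
    "write_bed",
]

_MT_SYNONYMS = {"M", "MT", "CHRM", "CHRMT"}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix and collapse mitochondrial synonyms.

    Ensembl names chromosomes ``1``..``22``/``X``/``MT`` while UCSC uses
    ``chr1``..``chrM``; mixing the two is the most common integration failure
    when combining gene models, regulatory builds and chain files, so every
    reader funnels through this function.
    """
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() in _MT_SYNONYMS:
        return "MT"
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize_pairs(pairs: np.ndarray) -> np.ndarray:
    """Sort and merge an (N, 2) array of [start, end) pairs.

    Intervals sharing only an endpoint are merged (the union of [a,b) and
    [b,c) is the contiguous run [a,c)); overlap queries elsewhere treat
    mere adjacency as non-overlap, consistent with half-open semantics.
    """
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = pairs[np.argsort(pairs[:, 0], kind="stable")]
    starts = pairs[:, 0]
    ends = np.maximum.accumulate(pairs[:, 1])
    # a new run starts where the start exceeds the running max end so far
    new_run = np.empty(len(pairs), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > ends[:-1]
    run_last = np.append(new_run[1:], True)
    out = np.empty((int(new_run.sum()), 2), dtype=np.int64)
    out[:, 0] = starts[new_run]
    out[:, 1] = ends[run_last]  # running max at the last member of each run
    return out


class IntervalSet:
    """A normalized set of genomic intervals, keyed by chromosome.

    Internally each chromosome maps to an ``(N, 2)`` int64 array of sorted,
    merged, pairwise-disjoint ``[start, end)`` rows, so set algebra and
    length accounting are exact integer operations.
    """

    __slots__ = ("_data",)

    def __init__(self, data: Mapping[str, np.ndarray] | None = None, *, _normalized: bool = False):
        self._data: Dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size == 0:
                    continue
                if np.any(arr[:, 0] >= arr[:, 1]) or np.any(arr[:, 0] < 0):
                    raise ValueError(f"invalid interval on {chrom}")
                self._data[chrom] = arr if _normalized else _normalize_pairs(arr)

    # ------------------------------------------------------------------ build
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        buckets: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return cls({c: np.array(v, dtype=np.int64) for c, v in buckets.items()})

    @classmethod
    def from_pairs(cls, chrom_pairs: Mapping[str, Sequence[Tuple[int, int]]]) -> "IntervalSet":
        return cls({c: np.array(v, dtype=np.int64) for c, v in chrom_pairs.items() if len(v)})

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    @classmethod
    def whole_genome(cls, chrom_lengths: Mapping[str, int]) -> "IntervalSet":
        return cls(
            {c: np.array([[0, n]], dtype=np.int64) for c, n in chrom_lengths.items() if n > 0},
            _normalized=True,
        )

    # ------------------------------------------------------------ inspection
    @property
    def chroms(self) -> List[str]:
        return sorted(self._data)

    def array(self, chrom: str) -> np.ndarray:
        """The (N, 2) interval array for one chromosome (possibly empty)."""
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for start, end in self._data[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    def __iter__(self) -> Iterator[GenomicInterval]:
        return self.intervals()

    def __bool__(self) -> bool:
        return bool(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        n = sum(len(a) for a in self._data.values())
        return f"IntervalSet({n} intervals on {len(self._data)} chromosomes, {self.total_length} bp)"

    @property
    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def length_by_chrom(self) -> Dict[str, int]:
        return {c: int((a[:, 1] - a[:, 0]).sum()) for c, a in self._data.items()}

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether base ``pos`` on ``chrom`` lies inside the set."""
        arr = self._data.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an array of positions."""
        arr = self._data.get(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if arr is None or arr.size == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < arr[:, 1][idx[ok]]
        return out

    def overlap_lengths(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Per-query overlap (in bp) between [starts, ends) spans and the set.

        Uses a prefix-sum over the chromosome's merged intervals, so a batch
        of queries costs two searchsorted passes.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        arr = self._data.get(chrom)
        if arr is None or arr.size == 0:
            return np.zeros(len(starts), dtype=np.int64)
        iv_starts, iv_ends = arr[:, 0], arr[:, 1]
        cum = np.concatenate([[0], np.cumsum(iv_ends - iv_starts)])

        def covered_before(pos: np.ndarray) -> np.ndarray:
            # total covered bp in (-inf, pos)
            i = np.searchsorted(iv_starts, pos, side="right")
            base = cum[i]
            # subtract the part of interval i-1 at or beyond pos
            has_prev = i > 0
            prev = np.where(has_prev, i - 1, 0)
            overhang = np.where(
                has_prev, np.clip(iv_ends[prev] - pos, 0, None), 0
            )
            return base - overhang

        return covered_before(ends) - covered_before(starts)

    # ------------------------------------------------------------ set algebra
    def union(self, other: "IntervalSet") -> "IntervalSet":
        chroms = set(self._data) | set(other._data)
        out = {}
        for c in chroms:
            merged = np.concatenate([self.array(c), other.array(c)])
            out[c] = merged
        return IntervalSet(out)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for c in set(self._data) & set(other._data):
            a, b = self._data[c], other._data[c]
            pairs = _intersect_arrays(a, b)
            if pairs.size:
                out[c] = pairs
        return IntervalSet(out, _normalized=True)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for c, a in self._data.items():
            b = other.array(c)
            if b.size == 0:
                out[c] = a.copy()
                continue
            pairs = _subtract_arrays(a, b)
            if pairs.size:
                out[c] = pairs
        return IntervalSet(out, _normalized=True)

    def complement(self, chrom_lengths: Mapping[str, int]) -> "IntervalSet":
        """All bases of the given chromosomes not in the set."""
        return IntervalSet.whole_genome(chrom_lengths).difference(self)

    def clip(self, chrom_lengths: Mapping[str, int]) -> "IntervalSet":
        """Restrict to [0, length) on each chromosome; drop unknown chromosomes."""
        return self.intersection(IntervalSet.whole_genome(chrom_lengths))

    def __or__(self, other: "IntervalSet") -> "IntervalSet":
        return self.union(other)

    def __and__(self, other: "IntervalSet") -> "IntervalSet":
        return self.intersection(other)

    def __sub__(self, other: "IntervalSet") -> "IntervalSet":
        return self.difference(other)

    @classmethod
    def union_all(cls, sets: Iterable["IntervalSet"]) -> "IntervalSet":
        buckets: Dict[str, List[np.ndarray]] = {}
        for s in sets:
            for c, a in s._data.items():
                buckets.setdefault(c, []).append(a)
        return cls({c: np.concatenate(arrs) for c, arrs in buckets.items()})


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two normalized (N,2) arrays via a two-pointer sweep."""
    out: List[Tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b, both normalized (N,2) arrays."""
    out: List[Tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------- I/O
def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into an IntervalSet."""
    buckets: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line with <3 fields: {line!r}")
            chrom = normalize_chrom(fields[0])
            buckets.setdefault(chrom, []).append((int(fields[1]), int(fields[2])))
    return IntervalSet.from_pairs(buckets)


def write_bed(ivset: IntervalSet, path, name: str | None = None) -> None:
    """Write an IntervalSet as BED3 (or BED4 when ``name`` is given)."""
    with open(path, "w") as fh:
        for iv in ivset:
            if name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
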