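"""Base-level coordinate projection through pairwise-alignment chains.

A UCSC chain file describes a pairwise genome alignment as scored chains of
gap-free blocks.  :func:`read_chain` expands each chain into its blocks,
converts negative-strand query coordinates onto the query (mouse) forward
strand, and resolves any overlapping reference coverage by keeping the
higher-scoring chain — a net-style, single-coverage-on-reference map, which
is what makes "the orthologous base" of a human position well defined.

The resulting :class:`AlignmentIndex` answers three questions:

* ``map_position`` — the mouse coordinate of one human base, or
  :data:`UNALIGNED`;
* ``map_interval`` — the run-length-compressed mouse image of an interval;
* ``aligned_mask`` — the subset of an interval set with an orthologous base,
  from which "fraction aligned" statistics are computed.

A human base is *aligned* if it falls inside any chain block, independent of
whether the aligned nucleotides differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import IntervalSet, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "UNALIGNED",
    "ChainBlock",
    "Chain",
    "AlignmentIndex",
    "read_chain",
    "write_chain",
]


class _Unaligned:
    """Sentinel for a reference base with no orthologous query base."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNALIGNED"

    def __bool__(self) -> bool:
        return False


UNALIGNED = _Unaligned()


@dataclass(frozen=True)
class ChainBlock:
    """One gap-free alignment block.

    Query coordinates are stored on the query forward strand regardless of
    the chain's strand; for a ``-`` block the first reference base pairs
    with the *last* forward-strand query base.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int  # forward strand
    qry_strand: str  # '+' or '-'
    chain_id: int
    score: float

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("empty chain block")
        if self.qry_strand not in "+-":
            raise ValueError(f"bad strand {self.qry_strand!r}")

    @property
    def size(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.size


@dataclass
class Chain:
    """A scored chain: ordered gap-free blocks between two genomes."""

    score: float
    ref_chrom: str
    ref_size: int
    qry_chrom: str
    qry_size: int
    qry_strand: str
    chain_id: int
    #: (ref_start, qry_forward_start, size) per block, in reference order
    blocks: List[Tuple[int, int, int]] = field(default_factory=list)


def read_chain(
    path,
    min_score: Optional[float] = None,
) -> "AlignmentIndex":
    """Parse a UCSC chain file into an :class:`AlignmentIndex`.

    Each chain's ``size dt dq`` body is expanded into gap-free blocks and
    validated against the header span; an inconsistent chain is rejected
    with its id in the message.  Overlapping reference coverage between
    chains is resolved by score (see :meth:`AlignmentIndex.from_blocks`).
    """
    blocks: List[ChainBlock] = []
    ref_sizes: Dict[str, int] = {}
    qry_sizes: Dict[str, int] = {}
    header: Optional[List[str]] = None
    t_pos = q_pos = 0
    chain_blocks: List[ChainBlock] = []

    def flush_chain(final_line: bool):
        nonlocal header, chain_blocks
        if header is None:
            return
        chain_id = int(header[12]) if len(header) > 12 else 0
        t_end, q_end = int(header[6]), int(header[11])
        if t_pos != t_end or q_pos != q_end:
            raise ValueError(
                f"chain {chain_id}: body size arithmetic inconsistent with header "
                f"(reached t={t_pos}/{t_end}, q={q_pos}/{q_end})"
            )
        if min_score is None or float(header[1]) >= min_score:
            blocks.extend(chain_blocks)
        header = None
        chain_blocks = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if header is not None:
                    raise ValueError(
                        f"{path}:{lineno}: chain header before previous chain ended"
                    )
                header = line.split()
                if len(header) < 12:
                    raise ValueError(f"{path}:{lineno}: truncated chain header")
                if header[4] != "+":
                    raise ValueError(
                        f"{path}:{lineno}: reference strand must be '+'"
                    )
                ref_sizes[normalize_chrom(header[2])] = int(header[3])
                qry_sizes[normalize_chrom(header[7])] = int(header[8])
                t_pos, q_pos = int(header[5]), int(header[10])
                continue
            if header is None:
                raise ValueError(f"{path}:{lineno}: alignment data outside a chain")
            parts = line.split()
            size = int(parts[0])
            dt = int(parts[1]) if len(parts) > 1 else 0
            dq = int(parts[2]) if len(parts) > 2 else 0
            if size > 0:
                chain_blocks.append(
                    _make_block(header, t_pos, q_pos, size)
                )
            t_pos += size + dt
            q_pos += size + dq
            if len(parts) == 1:
                flush_chain(True)
    flush_chain(False)
    return AlignmentIndex.from_blocks(blocks, ref_sizes=ref_sizes, qry_sizes=qry_sizes)


def _make_block(header: List[str], t_pos: int, q_pos: int, size: int) -> ChainBlock:
    strand = header[9]
    q_size = int(header[8])
    if strand == "+":
        fwd_start = q_pos
    else:
        # chain '-' coordinates count from the reversed strand:
        # reversed [q_pos, q_pos+size) is forward [q_size-q_pos-size, q_size-q_pos)
        fwd_start = q_size - (q_pos + size)
    return ChainBlock(
        ref_chrom=normalize_chrom(header[2]),
        ref_start=t_pos,
        ref_end=t_pos + size,
        qry_chrom=normalize_chrom(header[7]),
        qry_start=fwd_start,
        qry_strand=strand,
        chain_id=int(header[12]) if len(header) > 12 else 0,
        score=float(header[1]),
    )


def write_chain(chains: Iterable[Chain], path) -> None:
    """Write chains in UCSC chain format (blank-line terminated records)."""
    with open(path, "w") as fh:
        for ch in chains:
            if not ch.blocks:
                continue
            blocks = sorted(ch.blocks, key=lambda b: b[0])
            t_start = blocks[0][0]
            t_end = blocks[-1][0] + blocks[-1][2]
            if ch.qry_strand == "+":
                rev = [(fs, fs + sz) for _, fs, sz in blocks]
            else:
                rev = [(ch.qry_size - (fs + sz), ch.qry_size - fs) for _, fs, sz in blocks]
            q_start, q_end = rev[0][0], rev[-1][1]
            fh.write(
                f"chain {ch.score:g} {ch.ref_chrom} {ch.ref_size} + {t_start} {t_end} "
                f"{ch.qry_chrom} {ch.qry_size} {ch.qry_strand} {q_start} {q_end} {ch.chain_id}\n"
            )
            for i, (rs, _, sz) in enumerate(blocks):
                if i == len(blocks) - 1:
                    fh.write(f"{sz}\n")
                else:
                    dt = blocks[i + 1][0] - (rs + sz)
                    dq = rev[i + 1][0] - rev[i][1]
                    if dt < 0 or dq < 0:
                        raise ValueError(
                            f"chain {ch.chain_id}: blocks out of order (dt={dt}, dq={dq})"
                        )
                    fh.write(f"{sz} {dt} {dq}\n")
            fh.write("\n")


class AlignmentIndex:
    """Sorted, non-overlapping chain blocks, queryable in both directions."""

    def __init__(
        self,
        per_chrom: Dict[str, Dict[str, np.ndarray]],
        qry_chrom_names: List[str],
        ref_sizes: Dict[str, int],
        qry_sizes: Dict[str, int],
    ):
        self._per_chrom = per_chrom
        self._qry_names = qry_chrom_names
        self.ref_sizes = ref_sizes
        self.qry_sizes = qry_sizes
        self._ref_mask: Optional[IntervalSet] = None
        self._reverse: Optional[Dict[str, Dict[str, np.ndarray]]] = None

    # ------------------------------------------------------------ construction
    @classmethod
    def from_blocks(
        cls,
        blocks: Sequence[ChainBlock],
        ref_sizes: Mapping[str, int] | None = None,
        qry_sizes: Mapping[str, int] | None = None,
        resolve_overlaps: bool = True,
    ) -> "AlignmentIndex":
        """Build the index, enforcing single coverage on the reference.

        When two chains claim the same reference bases, the block from the
        higher-scoring chain wins and the lower-scoring block is truncated
        to the uncovered remainder (each truncation is logged).  Overlap
        that survives resolution is a hard error.
        """
        if resolve_overlaps:
            blocks = _resolve_overlaps(blocks)
        qry_names = sorted({b.qry_chrom for b in blocks})
        qry_index = {c: i for i, c in enumerate(qry_names)}
        per_chrom: Dict[str, Dict[str, np.ndarray]] = {}
        by_chrom: Dict[str, List[ChainBlock]] = {}
        for b in blocks:
            by_chrom.setdefault(b.ref_chrom, []).append(b)
        for chrom, bl in by_chrom.items():
            bl.sort(key=lambda b: b.ref_start)
            starts = np.array([b.ref_start for b in bl], dtype=np.int64)
            ends = np.array([b.ref_end for b in bl], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(
                    f"overlapping reference blocks remain on chromosome {chrom}"
                )
            per_chrom[chrom] = {
                "ref_start": starts,
                "ref_end": ends,
                "qry_start": np.array([b.qry_start for b in bl], dtype=np.int64),
                "strand": np.array([1 if b.qry_strand == "+" else -1 for b in bl], dtype=np.int8),
                "qry_chrom": np.array([qry_index[b.qry_chrom] for b in bl], dtype=np.int32),
                "chain_id": np.array([b.chain_id for b in bl], dtype=np.int64),
            }
        return cls(
            per_chrom,
            qry_names,
            dict(ref_sizes or {}),
            dict(qry_sizes or {}),
        )

    # --------------------------------------------------------------- inspection
    @property
    def ref_chroms(self) -> List[str]:
        return sorted(self._per_chrom)

    @property
    def n_blocks(self) -> int:
        return sum(len(d["ref_start"]) for d in self._per_chrom.values())

    def blocks(self) -> List[ChainBlock]:
        out = []
        for chrom in self.ref_chroms:
            d = self._per_chrom[chrom]
            for i in range(len(d["ref_start"])):
                out.append(
                    ChainBlock(
                        ref_chrom=chrom,
                        ref_start=int(d["ref_start"][i]),
                        ref_end=int(d["ref_end"][i]),
                        qry_chrom=self._qry_names[d["qry_chrom"][i]],
                        qry_start=int(d["qry_start"][i]),
                        qry_strand="+" if d["strand"][i] > 0 else "-",
                        chain_id=int(d["chain_id"][i]),
                        score=0.0,
                    )
                )
        return out

    @property
    def ref_mask(self) -> IntervalSet:
        """Union of all reference block spans (the aligned bases)."""
        if self._ref_mask is None:
            self._ref_mask = IntervalSet(
                {
                    c: np.column_stack([d["ref_start"], d["ref_end"]])
                    for c, d in self._per_chrom.items()
                }
            )
        return self._ref_mask

    # ------------------------------------------------------------------ queries
    def map_position(self, chrom: str, pos: int):
        """Mouse (chrom, pos) of one human base, or :data:`UNALIGNED`.

        An unknown chromosome raises ``KeyError`` — distinct from
        UNALIGNED, which is an ordinary, countable outcome.
        """
        chrom = normalize_chrom(chrom)
        if chrom not in self._per_chrom:
            if chrom in self.ref_sizes:
                return UNALIGNED  # known chromosome, no alignment at all
            raise KeyError(f"unknown reference chromosome {chrom!r}")
        d = self._per_chrom[chrom]
        i = int(np.searchsorted(d["ref_start"], pos, side="right")) - 1
        if i < 0 or pos >= d["ref_end"][i]:
            return UNALIGNED
        off = pos - int(d["ref_start"][i])
        qc = self._qry_names[d["qry_chrom"][i]]
        if d["strand"][i] > 0:
            return qc, int(d["qry_start"][i]) + off
        size = int(d["ref_end"][i] - d["ref_start"][i])
        return qc, int(d["qry_start"][i]) + size - 1 - off

    def map_interval(self, chrom: str, start: int, end: int):
        """Project [start, end) through the alignment.

        Returns a list of ``(ref_start, ref_end, qry_chrom, qry_start,
        qry_end, strand)`` segments in reference order; the summed segment
        length is the number of aligned bases in the interval.
        """
        chrom = normalize_chrom(chrom)
        if chrom not in self._per_chrom:
            if chrom in self.ref_sizes:
                return []
            raise KeyError(f"unknown reference chromosome {chrom!r}")
        rs, re_, qc, qs, qe, st = self.project(
            chrom, np.array([start]), np.array([end])
        )
        return [
            (int(rs[i]), int(re_[i]), self._qry_names[qc[i]], int(qs[i]), int(qe[i]),
             "+" if st[i] > 0 else "-")
            for i in range(len(rs))
        ]

    def project(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized interval projection.

        For a batch of [start, end) reference spans, returns parallel arrays
        over all produced segments: clipped reference start/end, query
        chromosome index, query forward-strand start/end, and strand sign.
        """
        d = self._per_chrom.get(chrom)
        empty = (np.empty(0, dtype=np.int64),) * 5 + (np.empty(0, dtype=np.int8),)
        if d is None:
            return empty
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        lo = np.searchsorted(d["ref_end"], starts, side="right")
        hi = np.searchsorted(d["ref_start"], ends, side="left")
        counts = np.maximum(hi - lo, 0)
        total = int(counts.sum())
        if total == 0:
            return empty
        q_of = np.repeat(np.arange(len(starts)), counts)
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        block = np.repeat(lo, counts) + (np.arange(total) - offsets)
        rs = np.maximum(d["ref_start"][block], starts[q_of])
        re_ = np.minimum(d["ref_end"][block], ends[q_of])
        strand = d["strand"][block]
        qs = np.where(
            strand > 0,
            d["qry_start"][block] + (rs - d["ref_start"][block]),
            d["qry_start"][block] + (d["ref_end"][block] - re_),
        )
        qe = qs + (re_ - rs)
        return rs, re_, d["qry_chrom"][block], qs, qe, strand

    def qry_chrom_name(self, idx: int) -> str:
        return self._qry_names[idx]

    def reverse_map_position(self, qry_chrom: str, qry_pos: int):
        """Human (chrom, pos) of one mouse forward-strand base, or UNALIGNED."""
        qry_chrom = normalize_chrom(qry_chrom)
        if self._reverse is None:
            self._build_reverse()
        if qry_chrom not in self._reverse:
            if qry_chrom in self.qry_sizes:
                return UNALIGNED
            raise KeyError(f"unknown query chromosome {qry_chrom!r}")
        d = self._reverse[qry_chrom]
        i = int(np.searchsorted(d["qry_start"], qry_pos, side="right")) - 1
        if i < 0 or qry_pos >= d["qry_end"][i]:
            return UNALIGNED
        off = qry_pos - int(d["qry_start"][i])
        chrom = d["ref_chrom_names"][d["ref_chrom"][i]]
        if d["strand"][i] > 0:
            return chrom, int(d["ref_start"][i]) + off
        size = int(d["qry_end"][i] - d["qry_start"][i])
        return chrom, int(d["ref_start"][i]) + size - 1 - off

    def _build_reverse(self) -> None:
        ref_names = self.ref_chroms
        ref_index = {c: i for i, c in enumerate(ref_names)}
        buckets: Dict[str, List[Tuple[int, int, int, int, int]]] = {}
        for chrom, d in self._per_chrom.items():
            for i in range(len(d["ref_start"])):
                qc = self._qry_names[d["qry_chrom"][i]]
                size = int(d["ref_end"][i] - d["ref_start"][i])
                buckets.setdefault(qc, []).append(
                    (
                        int(d["qry_start"][i]),
                        int(d["qry_start"][i]) + size,
                        ref_index[chrom],
                        int(d["ref_start"][i]),
                        int(d["strand"][i]),
                    )
                )
        self._reverse = {}
        for qc, rows in buckets.items():
            rows.sort()
            self._reverse[qc] = {
                "qry_start": np.array([r[0] for r in rows], dtype=np.int64),
                "qry_end": np.array([r[1] for r in rows], dtype=np.int64),
                "ref_chrom": np.array([r[2] for r in rows], dtype=np.int32),
                "ref_start": np.array([r[3] for r in rows], dtype=np.int64),
                "strand": np.array([r[4] for r in rows], dtype=np.int8),
                "ref_chrom_names": ref_names,
            }

    # --------------------------------------------------------------- statistics
    def aligned_mask(self, intervals: IntervalSet) -> IntervalSet:
        """The subset of ``intervals`` with an orthologous query base."""
        return intervals & self.ref_mask

    def aligned_fraction(self, intervals: IntervalSet) -> float:
        denom = intervals.total_length
        if denom == 0:
            return float("nan")
        return self.aligned_mask(intervals).total_length / denom

    def per_chrom_aligned_fractions(self) -> pd.DataFrame:
        """Aligned bp and fraction per reference chromosome."""
        rows = []
        for chrom in sorted(self.ref_sizes) or self.ref_chroms:
            size = self.ref_sizes.get(chrom)
            d = self._per_chrom.get(chrom)
            aligned = int((d["ref_end"] - d["ref_start"]).sum()) if d else 0
            rows.append(
                {
                    "chrom": chrom,
                    "length": size,
                    "aligned_bp": aligned,
                    "fraction_aligned": aligned / size if size else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def _resolve_overlaps(blocks: Sequence[ChainBlock]) -> List[ChainBlock]:
    """Enforce single reference coverage: higher chain score wins.

    Blocks are admitted in descending score order (ties broken by chain id
    then coordinate, so resolution is deterministic); each later block is
    truncated to the reference bases not yet claimed, preserving the
    base-level correspondence of the surviving pieces.
    """
    occupied: Dict[str, IntervalSet] = {}
    out: List[ChainBlock] = []
    n_truncated = 0
    ordered = sorted(
        blocks, key=lambda b: (-b.score, b.chain_id, b.ref_chrom, b.ref_start)
    )
    for b in ordered:
        occ = occupied.get(b.ref_chrom, IntervalSet.empty())
        span = IntervalSet.from_pairs({b.ref_chrom: [(b.ref_start, b.ref_end)]})
        free = span - occ
        if free.total_length == b.size:
            out.append(b)
        else:
            n_truncated += 1
            for piece in free:
                if b.qry_strand == "+":
                    qs = b.qry_start + (piece.start - b.ref_start)
                else:
                    qs = b.qry_start + (b.ref_end - piece.end)
                out.append(
                    ChainBlock(
                        ref_chrom=b.ref_chrom,
                        ref_start=piece.start,
                        ref_end=piece.end,
                        qry_chrom=b.qry_chrom,
                        qry_start=qs,
                        qry_strand=b.qry_strand,
                        chain_id=b.chain_id,
                        score=b.score,
                    )
                )
            logger.info(
                "chain %d: block %s:%d-%d truncated to %d bp by higher-scoring chains",
                b.chain_id, b.ref_chrom, b.ref_start, b.ref_end, free.total_length,
            )
        occupied[b.ref_chrom] = occ | span
    if n_truncated:
        logger.warning("resolved reference overlap: %d blocks truncated", n_truncated)
    return out
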