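"""Genomic interval containers and overlap primitives.

All coordinates are 0-based half-open (BED convention). Overlap queries are
vectorized per chromosome; sizes in this package are modest (thousands of
intervals), so a chunked broadcast beats pulling in an interval-tree
dependency.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicIntervalSet",
    "overlap_pairs",
    "overlap_indicator",
    "nearest_tss_index",
]

_CHUNK = 1024  # rows of the query set broadcast at a time


@dataclass(frozen=True)
class GenomicIntervalSet:
    """An ordered collection of genomic intervals.

    Parameters
    ----------
    chrom, start, end
        Parallel arrays; ``start < end`` for every record, starts
        non-negative, chromosome names non-empty.
    name, strand
        Optional parallel arrays; strand entries must be in ``{+,-,.}``.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray | None = None
    strand: np.ndarray | None = None

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        if not (len(chrom) == len(start) == len(end)):
            raise ValueError("chrom/start/end lengths differ")
        if np.any(start < 0):
            raise ValueError("negative interval start")
        if np.any(start >= end):
            bad = int(np.argmax(start >= end))
            raise ValueError(
                f"interval with start >= end at record {bad}: "
                f"{chrom[bad]}:{start[bad]}-{end[bad]}"
            )
        if any(c == "" for c in chrom):
            raise ValueError("empty chromosome name")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if self.name is not None:
            object.__setattr__(self, "name", np.asarray(self.name, dtype=object))
        if self.strand is not None:
            strand = np.asarray(self.strand, dtype=object)
            if not set(strand) <= {"+", "-", "."}:
                raise ValueError("strand entries must be one of +, -, .")
            object.__setattr__(self, "strand", strand)

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_records(cls, records) -> "GenomicIntervalSet":
        """Build from an iterable of (chrom, start, end[, name[, strand]])."""
        records = list(records)
        chrom = [r[0] for r in records]
        start = [r[1] for r in records]
        end = [r[2] for r in records]
        name = [r[3] for r in records] if records and len(records[0]) > 3 else None
        strand = [r[4] for r in records] if records and len(records[0]) > 4 else None
        return cls(
            np.array(chrom, dtype=object),
            np.array(start, dtype=np.int64),
            np.array(end, dtype=np.int64),
            None if name is None else np.array(name, dtype=object),
            None if strand is None else np.array(strand, dtype=object),
        )

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, idx) -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            self.chrom[idx],
            self.start[idx],
            self.end[idx],
            None if self.name is None else self.name[idx],
            None if self.strand is None else self.strand[idx],
        )


def _by_chrom(intervals: GenomicIntervalSet) -> dict:
    out: dict = {}
    for i, c in enumerate(intervals.chrom):
        out.setdefault(c, []).append(i)
    return {c: np.asarray(ix, dtype=np.intp) for c, ix in out.items()}


def overlap_pairs(
    a: GenomicIntervalSet, b: GenomicIntervalSet
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ia, ib) of every pair of intervals that share >= 1 bp.

    Strand-ignored, any-overlap on half-open coordinates:
    a.start < b.end and b.start < a.end.
    """
    ia_out: list[np.ndarray] = []
    ib_out: list[np.ndarray] = []
    b_groups = _by_chrom(b)
    for c, ia in _by_chrom(a).items():
        ib = b_groups.get(c)
        if ib is None:
            continue
        b_start = b.start[ib]
        b_end = b.end[ib]
        for lo in range(0, len(ia), _CHUNK):
            ia_blk = ia[lo : lo + _CHUNK]
            hit = (a.start[ia_blk][:, None] < b_end[None, :]) & (
                b_start[None, :] < a.end[ia_blk][:, None]
            )
            r, c_ = np.nonzero(hit)
            ia_out.append(ia_blk[r])
            ib_out.append(ib[c_])
    if not ia_out:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    return np.concatenate(ia_out), np.concatenate(ib_out)


def overlap_indicator(a: GenomicIntervalSet, b: GenomicIntervalSet) -> np.ndarray:
    """Boolean len(b) vector: does each interval of ``b`` overlap any of ``a``."""
    _, ib = overlap_pairs(a, b)
    out = np.zeros(len(b), dtype=bool)
    out[ib] = True
    return out


def nearest_tss_index(
    regions: GenomicIntervalSet, tss: np.ndarray, tss_chrom: np.ndarray
) -> np.ndarray:
    """Nearest-gene assignment by |TSS - region midpoint| on the same chromosome.

    Ties resolved toward the smaller TSS coordinate (then smaller gene index).
    Regions on chromosomes with no annotated gene get -1.
    """
    tss = np.asarray(tss, dtype=np.int64)
    out = np.full(len(regions), -1, dtype=np.intp)
    gene_groups: dict = {}
    for i, c in enumerate(tss_chrom):
        gene_groups.setdefault(c, []).append(i)
    mids = (regions.start + regions.end) // 2
    for c, ridx in _by_chrom(regions).items():
        gidx = gene_groups.get(c)
        if gidx is None:
            continue
        gidx = np.asarray(gidx, dtype=np.intp)
        # order genes by (tss, index) so argmin returns the tie-break winner
        order = gidx[np.lexsort((gidx, tss[gidx]))]
        dist = np.abs(tss[order][None, :] - mids[ridx][:, None])
        out[ridx] = order[np.argmin(dist, axis=1)]
    return out
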