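"""Genomic interval primitives and BED/bedGraph/annotation I/O.

Everything downstream — gene windows, read counting, consensus peaks,
stranded enhancer sites — is built on one interval type with BED
conventions: 0-based, half-open coordinates, strand one of ``+``, ``-`` or
``.`` (unstranded).  Read collections are held in :class:`ReadSet`, which
keeps per-(chromosome, strand) sorted coordinate arrays so that overlap
counting over many windows is a pair of binary searches per window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

__all__ = [
    "StrandedInterval",
    "GeneModel",
    "ReadSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_annotation",
    "write_bedgraph",
    "coverage_from_reads",
    "merge_intervals",
    "closest_distance",
    "count_overlapping_reads",
]


@dataclass(frozen=True, order=True)
class StrandedInterval:
    """A genomic interval: 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "StrandedInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "StrandedInterval") -> float:
        """Edge-to-edge gap in bp; 0 if overlapping; inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class GeneModel:
    """A refGene-style annotation record (whole transcription unit)."""

    name: str
    interval: StrandedInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start site."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class BedParseError(ValueError):
    """Raised on a malformed BED line; message names the line number."""


class ReadSet:
    """A collection of mapped reads with fast strand-aware overlap counting.

    ``total_mapped`` is the depth-normalisation denominator (reads per
    million) and ``genome_length`` the reference size used by the Poisson
    background model; neither needs to equal the number of stored reads.
    """

    def __init__(
        self,
        reads: Iterable[StrandedInterval] | None = None,
        total_mapped: int | None = None,
        genome_length: int = 0,
        *,
        _arrays: dict | None = None,
    ) -> None:
        if _arrays is not None:
            self._arr = _arrays
        else:
            self._arr = {}
            buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
            for r in reads or []:
                buckets.setdefault((r.chrom, r.strand), []).append((r.start, r.end))
            for key, pairs in buckets.items():
                a = np.asarray(pairs, dtype=np.int64)
                order = np.lexsort((a[:, 1], a[:, 0]))
                a = a[order]
                self._arr[key] = (a[:, 0].copy(), a[:, 1].copy())
        n = sum(len(s) for s, _ in self._arr.values())
        self.total_mapped = int(total_mapped) if total_mapped is not None else n
        self.genome_length = int(genome_length)
        # per-key ends sorted independently, for the counting identity
        self._ends_sorted = {k: np.sort(e) for k, (s, e) in self._arr.items()}

    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray,
        total_mapped: int | None = None,
        genome_length: int = 0,
    ) -> "ReadSet":
        """Build from parallel numpy arrays on a single chromosome."""
        arr = {}
        for s in ("+", "-", "."):
            m = strands == s
            if not m.any():
                continue
            st, en = np.asarray(starts[m], dtype=np.int64), np.asarray(
                ends[m], dtype=np.int64
            )
            order = np.lexsort((en, st))
            arr[(chrom, s)] = (st[order], en[order])
        return cls(
            total_mapped=total_mapped
            if total_mapped is not None
            else int(sum(len(a[0]) for a in arr.values())),
            genome_length=genome_length,
            _arrays=arr,
        )

    @classmethod
    def pooled(
        cls,
        readsets: Sequence["ReadSet"],
        total_mapped: int | None = None,
        genome_length: int | None = None,
    ) -> "ReadSet":
        """Fast concatenation of several read sets (array-level merge)."""
        arr: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        keys = {k for rs in readsets for k in rs._arr}
        for key in keys:
            starts = np.concatenate(
                [rs._arr[key][0] for rs in readsets if key in rs._arr]
            )
            ends = np.concatenate(
                [rs._arr[key][1] for rs in readsets if key in rs._arr]
            )
            order = np.lexsort((ends, starts))
            arr[key] = (starts[order], ends[order])
        return cls(
            total_mapped=total_mapped
            if total_mapped is not None
            else sum(rs.total_mapped for rs in readsets),
            genome_length=genome_length
            if genome_length is not None
            else max((rs.genome_length for rs in readsets), default=0),
            _arrays=arr,
        )

    def to_frame(self) -> pd.DataFrame:
        """All reads as a (chrom, start, end, strand) frame, sorted."""
        parts = []
        for (chrom, strand), (starts, ends) in sorted(self._arr.items()):
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "strand": strand}
                )
            )
        if not parts:
            return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        total_mapped: int | None = None,
        genome_length: int = 0,
    ) -> "ReadSet":
        """Fast BED6 reader for large read files (no per-line validation)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            comment="#",
        )
        arr: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            order = np.lexsort((ends, starts))
            arr[(str(chrom), str(strand))] = (starts[order], ends[order])
        return cls(
            total_mapped=total_mapped
            if total_mapped is not None
            else len(df),
            genome_length=genome_length,
            _arrays=arr,
        )

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._arr.values())

    def iter_reads(self) -> Iterable[StrandedInterval]:
        for (chrom, strand), (starts, ends) in sorted(self._arr.items()):
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield StrandedInterval(chrom, s, e, strand)

    def count(self, window: StrandedInterval, strand_specific: bool = True) -> int:
        """Number of reads overlapping ``window`` by >= 1 bp.

        With ``strand_specific`` only reads on the window's strand count;
        an unstranded window always counts both strands.
        """
        if strand_specific and window.strand != ".":
            keys = [(window.chrom, window.strand)]
        else:
            keys = [(window.chrom, s) for s in STRANDS]
        total = 0
        for key in keys:
            if key not in self._arr:
                continue
            starts, _ = self._arr[key]
            ends_sorted = self._ends_sorted[key]
            # reads with start < window.end, minus reads with end <= window.start
            total += int(
                np.searchsorted(starts, window.end, side="left")
                - np.searchsorted(ends_sorted, window.start, side="right")
            )
        return total

    def count_many(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        strand: str,
    ) -> np.ndarray:
        """Vectorised :meth:`count` for many same-strand windows."""
        if strand == ".":
            keys = [(chrom, s) for s in STRANDS]
        else:
            keys = [(chrom, strand)]
        out = np.zeros(len(starts), dtype=np.int64)
        for key in keys:
            if key not in self._arr:
                continue
            rstarts, _ = self._arr[key]
            rends = self._ends_sorted[key]
            out += np.searchsorted(rstarts, ends, side="left") - np.searchsorted(
                rends, starts, side="right"
            )
        return out


# ---------------------------------------------------------------------------
# BED / annotation readers and writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, min_fields: int = 3) -> list[StrandedInterval]:
    """Parse a BED3+/BED6 file into intervals.

    Strand is taken from field 6 when present, else unstranded. Comment,
    ``track`` and ``browser`` lines are skipped. Raises
    :class:`BedParseError` naming the offending line on malformed input.
    """
    out: list[StrandedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(StrandedInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[StrandedInterval], path: str | Path) -> None:
    """Write BED6 (name '.', score 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a refGene-style tab table with columns name, chrom, strand, txStart, txEnd.

    A header row is required; extra columns are ignored. Coordinates are
    0-based half-open (UCSC txStart is already 0-based).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chrom", "strand", "txStart", "txEnd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                name=str(row.name),
                interval=StrandedInterval(
                    str(row.chrom), int(row.txStart), int(row.txEnd), str(row.strand)
                ),
            )
        )
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        (g.name, g.chrom, g.strand, g.interval.start, g.interval.end) for g in genes
    ]
    pd.DataFrame(rows, columns=["name", "chrom", "strand", "txStart", "txEnd"]).to_csv(
        path, sep="\t", index=False
    )


def coverage_from_reads(reads: ReadSet) -> dict[tuple[str, str], np.ndarray]:
    """Per-base coverage arrays keyed by (chrom, strand)."""
    cov: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), (starts, ends) in reads._arr.items():
        if len(starts) == 0:
            continue
        size = int(ends.max())
        delta = np.zeros(size + 1, dtype=np.int64)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        cov[(chrom, strand)] = np.cumsum(delta)[:-1]
    return cov


def write_bedgraph(
    coverage_by_position: Mapping[tuple[str, str], np.ndarray],
    total_mapped: int,
    path: str | Path,
) -> None:
    """Write strand-signed, depth-normalised bedGraph.

    Values are raw coverage divided by millions of mapped reads; minus-strand
    values are written as negative numbers. Zero-coverage runs are omitted.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0 for bedGraph normalisation")
    scale = total_mapped / 1e6
    with open(path, "w") as fh:
        for (chrom, strand), cov in sorted(coverage_by_position.items()):
            cov = np.asarray(cov)
            if cov.size == 0:
                continue
            # run-length encode
            change = np.nonzero(np.diff(cov))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            sign = -1.0 if strand == "-" else 1.0
            for s, e in zip(starts.tolist(), ends.tolist()):
                v = cov[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{sign * v / scale:g}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[StrandedInterval], bookended: bool = True
) -> list[StrandedInterval]:
    """Union-merge intervals per chromosome, ignoring strand.

    With ``bookended`` (the bedtools merge default), touching intervals
    (end == next start) also merge. Output is sorted and unstranded.
    """
    by_chrom: dict[str, list[StrandedInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[StrandedInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            joins = iv.start <= cur_e if bookended else iv.start < cur_e
            if joins:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(StrandedInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(StrandedInterval(chrom, cur_s, cur_e))
    return merged


def closest_distance(
    query: StrandedInterval, subjects: Sequence[StrandedInterval]
) -> tuple[float, StrandedInterval | None]:
    """Distance in bp to the nearest subject (0 if overlapping).

    Ties break to the leftmost subject start. When no subject shares the
    query's chromosome the sentinel (inf, None) is returned so callers can
    treat such queries as maximally distal.
    """
    if not subjects:
        raise ValueError("closest_distance: subjects must be non-empty")
    best: tuple[float, int, int] | None = None  # (distance, start, index)
    for i, s in enumerate(subjects):
        if s.chrom != query.chrom:
            continue
        d = query.distance_to(s)
        key = (d, s.start, i)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return math.inf, None
    return best[0], subjects[best[2]]


def count_overlapping_reads(
    window: StrandedInterval, reads: ReadSet, strand_specific: bool = True
) -> int:
    """Reads overlapping the window by >= 1 bp (coverageBed semantics)."""
    return reads.count(window, strand_specific=strand_specific)
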