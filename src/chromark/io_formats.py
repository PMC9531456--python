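"""Interval and matrix I/O with strict 0-based half-open coordinates.

All coordinates inside the package are 0-based half-open (UCSC BED
convention); conversion, if any, happens only at file boundaries.
Chromosome names are taken verbatim — no ``chr`` normalization — and a
chromosome present in one input but absent from another is an error, not
a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "GenomeAnnotation",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "merge_intervals",
    "total_bp",
    "overlap_bp",
    "intervals_to_frame",
    "frame_to_intervals",
]


class FormatError(ValueError):
    """Raised for malformed interval/track files, with the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class SignalTrack:
    """bedGraph-semantics coverage: per chromosome, sorted non-overlapping
    intervals with non-negative values.

    Stored as parallel numpy arrays per chromosome for fast arithmetic.
    """

    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            self._validate_chrom(chrom, starts, ends, values)
            keep = values != 0
            self.data[chrom] = (starts[keep], ends[keep], values[keep])

    def _validate_chrom(self, chrom, starts, ends, values) -> None:
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("ragged arrays")
        if len(starts) == 0:
            return
        if np.any(starts >= ends) or np.any(starts < 0):
            raise ValueError(f"{chrom}: require 0 <= start < end")
        if np.any(values < 0):
            raise ValueError(f"{chrom}: negative signal value")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: intervals overlap or are unsorted")
        if self.chrom_sizes is not None:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if ends[-1] > self.chrom_sizes[chrom]:
                raise ValueError(f"{chrom}: interval beyond chromosome end")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def total_signal(self) -> float:
        """Sum of value x width over the whole track (the library size)."""
        return float(
            sum(
                ((e - s) * v).sum()
                for s, e, v in self.data.values()
            )
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        for c in self.data:
            for a, b in zip(self.data[c], other.data[c]):
                if not np.array_equal(a, b):
                    return False
        return True


@dataclass
class GenomeAnnotation:
    """Gene models plus CGI intervals and derived element sets.

    ``genes`` columns: gene_id, chrom, strand, tss, gene_start, gene_end,
    length, biotype, housekeeping.  Element sets are interval DataFrames
    with columns chrom/start/end/name (and class-specific extras).
    """

    genes: pd.DataFrame
    cgi: pd.DataFrame
    chrom_sizes: dict[str, int]
    elements: dict[str, pd.DataFrame] = field(default_factory=dict)
    promoter_halfwidth: int = 2000

    def promoters(self) -> pd.DataFrame:
        """Promoter = [TSS-2000, TSS+2000) clipped to the chromosome,
        labeled CGI iff it intersects a CGI interval by >= 1 bp."""
        g = self.genes
        starts = np.maximum(g["tss"].to_numpy() - self.promoter_halfwidth, 0)
        ends = np.minimum(
            g["tss"].to_numpy() + self.promoter_halfwidth,
            g["chrom"].map(self.chrom_sizes).to_numpy(),
        )
        prom = pd.DataFrame(
            {
                "chrom": g["chrom"].to_numpy(),
                "start": starts,
                "end": ends,
                "name": g["gene_id"].to_numpy(),
                "gene_id": g["gene_id"].to_numpy(),
                "housekeeping": g["housekeeping"].to_numpy(),
            }
        )
        cgi_by_chrom = {
            c: merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()
            )
            for c, sub in self.cgi.groupby("chrom")
        }
        is_cgi = np.zeros(len(prom), dtype=bool)
        for i, row in enumerate(prom.itertuples(index=False)):
            m = cgi_by_chrom.get(row.chrom)
            if m is None:
                continue
            s, e = m
            j = np.searchsorted(e, row.start, side="right")
            is_cgi[i] = j < len(s) and s[j] < row.end
        prom["cgi"] = is_cgi
        return prom


# ---------------------------------------------------------------------------
# file readers / writers

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_bedgraph(path, chrom_sizes: Mapping[str, int] | None = None) -> SignalTrack:
    """Parse a 4-column bedGraph into a validated :class:`SignalTrack`.

    Zero-valued rows are dropped; overlapping rows, negative values and
    inverted coordinates are rejected with the offending line number.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=np.float64)
        if np.any(starts[1:] < ends[:-1]):
            bad = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
            raise FormatError(
                f"{path}: overlapping intervals on {chrom} near "
                f"{starts[bad + 1]}"
            )
        data[chrom] = (starts, ends, values)
    return SignalTrack(data, chrom_sizes=chrom_sizes)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bed(path, n_fields: int | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6; strand and name are kept when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            k = n_fields or len(fields)
            if k < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if k >= 4 and len(fields) >= 4 else None
            value = None
            if k >= 5 and len(fields) >= 5:
                try:
                    value = float(fields[4])
                except ValueError:
                    value = None
            strand = fields[5] if k >= 6 and len(fields) >= 6 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand, name, value)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.value:g}" if iv.value is not None else "0"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# interval arithmetic

def merge_intervals(
    starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals on one chromosome.

    Returns sorted, disjoint (starts, ends). Touching intervals merge.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _group_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: merge_intervals(
            np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
        )
        for c, pairs in per.items()
    }


def total_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total base pairs covered by the merged union of ``intervals``."""
    n = 0
    for s, e in _group_by_chrom(intervals).values():
        n += int((e - s).sum())
    return n


def overlap_bp(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> int:
    """Base pairs in the intersection of the two merged interval sets."""
    a = _group_by_chrom(set_a)
    b = _group_by_chrom(set_b)
    total = 0
    for chrom in set(a) & set(b):
        sa, ea = a[chrom]
        sb, eb = b[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return total


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name if iv.name is not None else "." for iv in intervals],
            "strand": [iv.strand for iv in intervals],
        }
    )


def frame_to_intervals(frame: pd.DataFrame) -> list[GenomicInterval]:
    has_name = "name" in frame.columns
    has_strand = "strand" in frame.columns
    return [
        GenomicInterval(
            str(row.chrom),
            int(row.start),
            int(row.end),
            str(getattr(row, "strand", ".")) if has_strand else ".",
            str(getattr(row, "name", None)) if has_name else None,
        )
        for row in frame.itertuples(index=False)
    ]
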