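"""Sparse-background peak calling and region quantification.

Replicate tracks are combined by mean over the union of their
breakpoints; stringent peak calling scores maximal runs of contiguous
nonzero coverage by total signal (AUC = sum of value x width) and keeps
the nearest-rank top fraction (ties at the threshold retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    SignalTrack,
    merge_intervals,
)

__all__ = [
    "Peak",
    "PeakSet",
    "QuantMatrix",
    "merge_replicates",
    "call_peaks_stringent",
    "filter_blacklist",
    "union_peaks",
    "quantify",
    "normalize",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    auc: float
    max_value: float
    summit: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    peaks: list[Peak]
    sample: str = ""
    top_fraction: float | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start))
        prev: Peak | None = None
        for p in self.peaks:
            if p.auc <= 0:
                raise ValueError(f"peak {p.chrom}:{p.start}-{p.end} has auc <= 0")
            if prev is not None and prev.chrom == p.chrom and p.start < prev.end:
                raise ValueError("peaks overlap")
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(p.chrom, p.start, p.end, name=f"peak{i + 1}", value=p.auc)
            for i, p in enumerate(self.peaks)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [f"peak{i + 1}" for i in range(len(self.peaks))],
                "auc": [p.auc for p in self.peaks],
                "summit": [p.summit for p in self.peaks],
            }
        )


def merge_replicates(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Mean coverage over the union of replicate breakpoints.

    A replicate with no interval at a position contributes 0 to the mean,
    so the result is defined over the union of supports.
    """
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    if len(tracks) == 1:
        return tracks[0]
    chroms = sorted({c for t in tracks for c in t.data})
    sizes = None
    for t in tracks:
        if t.chrom_sizes is not None:
            sizes = t.chrom_sizes
            break
    out = {}
    n = len(tracks)
    for chrom in chroms:
        bps = set()
        for t in tracks:
            if chrom in t.data:
                s, e, _ = t.data[chrom]
                bps.update(s.tolist())
                bps.update(e.tolist())
        grid = np.array(sorted(bps), dtype=np.int64)
        if len(grid) < 2:
            continue
        seg_start, seg_end = grid[:-1], grid[1:]
        total = np.zeros(len(seg_start))
        for t in tracks:
            if chrom not in t.data:
                continue
            s, e, v = t.data[chrom]
            # segment belongs to interval i if s[i] <= seg_start < e[i]
            idx = np.searchsorted(s, seg_start, side="right") - 1
            ok = (idx >= 0) & (seg_start < e[np.clip(idx, 0, None)])
            total[ok] += v[idx[ok]]
        mean = total / n
        out[chrom] = (seg_start, seg_end, mean)
    return SignalTrack(out, chrom_sizes=sizes)


def call_peaks_stringent(
    track: SignalTrack, top_fraction: float = 0.01, sample: str = ""
) -> PeakSet:
    """Call signal blocks and keep the top fraction by AUC.

    Blocks are maximal runs of contiguous (gap 0) nonzero intervals.
    Retains the ceil(top_fraction * n_blocks) highest-AUC blocks by
    nearest rank; blocks tied with the threshold AUC are all kept.
    An all-zero track yields an empty PeakSet.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    blocks: list[Peak] = []
    for chrom in track.chroms:
        starts, ends, values = track.data[chrom]
        if len(starts) == 0:
            continue
        # split where the next interval does not start at the current end
        breaks = np.flatnonzero(starts[1:] != ends[:-1]) + 1
        run_starts = np.concatenate(([0], breaks))
        run_ends = np.concatenate((breaks, [len(starts)]))
        for a, b in zip(run_starts, run_ends):
            w = ends[a:b] - starts[a:b]
            auc = float((values[a:b] * w).sum())
            k = int(np.argmax(values[a:b]))
            summit = int((starts[a + k] + ends[a + k]) // 2)
            blocks.append(
                Peak(
                    chrom=chrom,
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    auc=auc,
                    max_value=float(values[a:b].max()),
                    summit=summit,
                )
            )
    if not blocks:
        return PeakSet([], sample=sample, top_fraction=top_fraction)
    n_keep = math.ceil(top_fraction * len(blocks))
    aucs = sorted((p.auc for p in blocks), reverse=True)
    threshold = aucs[n_keep - 1]
    kept = [p for p in blocks if p.auc >= threshold]
    return PeakSet(kept, sample=sample, top_fraction=top_fraction)


def filter_blacklist(
    peaks: PeakSet, blacklist: Sequence[GenomicInterval]
) -> PeakSet:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in blacklist:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {
        c: merge_intervals(
            np.array([p[0] for p in v]), np.array([p[1] for p in v])
        )
        for c, v in per.items()
    }
    kept = []
    for p in peaks:
        m = merged.get(p.chrom)
        if m is not None:
            s, e = m
            j = np.searchsorted(e, p.start, side="right")
            if j < len(s) and s[j] < p.end:
                continue
        kept.append(p)
    return PeakSet(kept, sample=peaks.sample, top_fraction=peaks.top_fraction)


def union_peaks(peaksets: Sequence[PeakSet]) -> list[GenomicInterval]:
    """Merged union of peak intervals across samples (the master list)."""
    if len(peaksets) == 0:
        raise ValueError("need at least one PeakSet")
    per: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for p in ps:
            per.setdefault(p.chrom, []).append((p.start, p.end))
    out: list[GenomicInterval] = []
    i = 0
    for chrom in sorted(per):
        s, e = merge_intervals(
            np.array([p[0] for p in per[chrom]]),
            np.array([p[1] for p in per[chrom]]),
        )
        for a, b in zip(s, e):
            i += 1
            out.append(GenomicInterval(chrom, int(a), int(b), name=f"region{i}"))
    return out


@dataclass
class QuantMatrix:
    """Regions x samples signal matrix with its normalization state."""

    regions: pd.DataFrame  # chrom, start, end, name
    counts: pd.DataFrame  # index = region name, columns = sample names
    library_sizes: dict[str, float]
    normalization: str = "raw"  # raw | CPM | RPKM | log2CPM | log2RPKM

    def __post_init__(self) -> None:
        if self.normalization == "raw" and (self.counts.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def lengths(self) -> np.ndarray:
        return (self.regions["end"] - self.regions["start"]).to_numpy()


def _region_signal(track: SignalTrack, regions: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(regions))
    cum = {}
    for chrom, (s, e, v) in track.data.items():
        # prefix sums of value*width let each region query run in O(log n)
        widths = (e - s) * v
        cum[chrom] = (s, e, v, np.concatenate(([0.0], np.cumsum(widths))))
    for i, row in enumerate(regions.itertuples(index=False)):
        entry = cum.get(row.chrom)
        if entry is None:
            continue
        s, e, v, pref = entry
        lo = np.searchsorted(e, row.start, side="right")
        hi = np.searchsorted(s, row.end, side="left")
        if lo >= hi:
            continue
        total = pref[hi] - pref[lo]
        # trim partially-overlapping flanking intervals
        total -= max(0, row.start - s[lo]) * v[lo]
        total -= max(0, e[hi - 1] - row.end) * v[hi - 1]
        out[i] = total
    return out


def tile_genome(chrom_sizes: Mapping[str, int], tile: int = 3000) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for s in range(0, size, tile):
            e = min(s + tile, size)
            rows.append((chrom, s, e, f"{chrom}:{s}-{e}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def quantify(
    tracks: Mapping[str, SignalTrack],
    regions: Sequence[GenomicInterval] | pd.DataFrame | None = None,
    tile: int | None = None,
) -> QuantMatrix:
    """Sum value x width of each track over each region.

    Pass ``tile`` to quantify genome-wide fixed-width bins instead of an
    explicit region list. Library size is the track's total signal.
    """
    if (regions is None) == (tile is None):
        raise ValueError("provide exactly one of regions or tile")
    if tile is not None:
        sizes = None
        for t in tracks.values():
            if t.chrom_sizes is not None:
                sizes = t.chrom_sizes
                break
        if sizes is None:
            raise ValueError("tiling requires chromosome sizes on a track")
        region_df = tile_genome(sizes, tile)
    elif isinstance(regions, pd.DataFrame):
        region_df = regions.reset_index(drop=True)
    else:
        region_df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in regions],
                "start": [r.start for r in regions],
                "end": [r.end for r in regions],
                "name": [
                    r.name if r.name else f"region{i + 1}"
                    for i, r in enumerate(regions)
                ],
            }
        )
    for row in region_df.itertuples(index=False):
        for t in tracks.values():
            if t.chrom_sizes is not None:
                if row.chrom not in t.chrom_sizes:
                    raise ValueError(f"unknown chromosome {row.chrom!r}")
                if row.end > t.chrom_sizes[row.chrom]:
                    raise ValueError(
                        f"region {row.name} extends beyond {row.chrom}"
                    )
    counts = pd.DataFrame(
        {name: _region_signal(t, region_df) for name, t in tracks.items()},
        index=region_df["name"].to_numpy(),
    )
    lib = {name: t.total_signal() for name, t in tracks.items()}
    return QuantMatrix(regions=region_df, counts=counts, library_sizes=lib)


def normalize(
    matrix: QuantMatrix, mode: str, pseudocount: float = 1.0
) -> QuantMatrix:
    """CPM / RPKM normalization with optional log2(x + pseudocount)."""
    if matrix.normalization != "raw":
        raise ValueError("normalize expects a raw matrix")
    if mode not in ("CPM", "RPKM", "log2CPM", "log2RPKM"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = matrix.counts.copy().astype(float)
    for sample in counts.columns:
        lib = matrix.library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"zero library size for {sample!r}")
        counts[sample] = counts[sample] * 1e6 / lib
        if "RPKM" in mode:
            counts[sample] = counts[sample] * 1e3 / matrix.lengths
    if mode.startswith("log2"):
        counts = np.log2(counts + pseudocount)
    return QuantMatrix(
        regions=matrix.regions,
        counts=counts,
        library_sizes=matrix.library_sizes,
        normalization=mode,
    )
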