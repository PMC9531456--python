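"""Peak-to-feature annotation and overlap-enrichment statistics.

Each peak receives exactly one feature label by fixed priority
(promoter > 5'UTR > exon > intron > 3'UTR > downstream > intergenic),
where an overlap of a single base pair counts.  Two enrichment
statistics are exposed:

* ``feature_fold_enrichment`` — overlap_bp * genome_size /
  (peak_bp * feature_bp), on merged sets;
* ``pairwise_set_enrichment`` — overlap_bp / (setA_bp * setB_bp),
  with a column-wise z-scaling helper for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeAnnotation,
    GenomicInterval,
    overlap_bp,
    total_bp,
)
from .peaks import PeakSet

__all__ = [
    "FEATURE_PRIORITY",
    "FeatureCatalog",
    "build_feature_catalog",
    "annotate_peaks",
    "feature_fold_enrichment",
    "pairwise_set_enrichment",
    "enrichment_matrix",
    "zscale_columns",
    "fraction_covered",
    "tss_profile",
]

FEATURE_PRIORITY = (
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "downstream",
)

DOWNSTREAM_BP = 3000  # conventional window past the gene end
UTR_BP = 200
TERMINAL_EXON_BP = 500


@dataclass
class FeatureCatalog:
    features: dict[str, list[GenomicInterval]]
    genome_size: int
    annotation: GenomeAnnotation | None = None

    def feature_bp(self, name: str) -> int:
        return total_bp(self.features[name])


def build_feature_catalog(annotation: GenomeAnnotation) -> FeatureCatalog:
    """Derive feature sets from gene models.

    Gene models carry no exon structure, so a deterministic toy gene
    anatomy is used: terminal exons at each end of the gene body with
    short UTRs inside them, intron in between.
    """
    feats: dict[str, list[GenomicInterval]] = {
        k: []
        for k in (
            "promoter", "CGI_promoter", "nonCGI_promoter", "five_prime_utr",
            "exon", "intron", "three_prime_utr", "downstream", "CGI",
        )
    }
    prom = annotation.promoters()
    for row in prom.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), name=row.gene_id)
        feats["promoter"].append(iv)
        feats["CGI_promoter" if row.cgi else "nonCGI_promoter"].append(iv)
    for g in annotation.genes.itertuples(index=False):
        size = annotation.chrom_sizes[g.chrom]
        start, end = int(g.gene_start), int(g.gene_end)
        left_exon = (start, min(start + TERMINAL_EXON_BP, end))
        right_exon = (max(end - TERMINAL_EXON_BP, start), end)
        five, three = (left_exon, right_exon) if g.strand == "+" else (
            right_exon, left_exon
        )
        feats["exon"].append(GenomicInterval(g.chrom, *left_exon))
        if right_exon[0] > left_exon[1]:
            feats["exon"].append(GenomicInterval(g.chrom, *right_exon))
            feats["intron"].append(
                GenomicInterval(g.chrom, left_exon[1], right_exon[0])
            )
        if five[1] > five[0]:
            utr5 = (five[0], min(five[0] + UTR_BP, five[1])) if g.strand == "+" \
                else (max(five[1] - UTR_BP, five[0]), five[1])
            feats["five_prime_utr"].append(GenomicInterval(g.chrom, *utr5))
        if three[1] > three[0]:
            utr3 = (max(three[1] - UTR_BP, three[0]), three[1]) if g.strand == "+" \
                else (three[0], min(three[0] + UTR_BP, three[1]))
            feats["three_prime_utr"].append(GenomicInterval(g.chrom, *utr3))
        if g.strand == "+":
            ds = (end, min(end + DOWNSTREAM_BP, size))
        else:
            ds = (max(start - DOWNSTREAM_BP, 0), start)
        if ds[1] > ds[0]:
            feats["downstream"].append(GenomicInterval(g.chrom, *ds))
    for row in annotation.cgi.itertuples(index=False):
        feats["CGI"].append(GenomicInterval(row.chrom, int(row.start), int(row.end)))
    genome_size = int(sum(annotation.chrom_sizes.values()))
    return FeatureCatalog(features=feats, genome_size=genome_size,
                          annotation=annotation)


def _overlaps_any(
    iv_chrom: str, iv_start: int, iv_end: int,
    intervals: Sequence[GenomicInterval],
) -> bool:
    for f in intervals:
        if f.chrom == iv_chrom and f.start < iv_end and f.end > iv_start:
            return True
    return False


def annotate_peaks(peaks: PeakSet, catalog: FeatureCatalog) -> pd.DataFrame:
    """One feature label per peak by priority, plus signed strand-aware
    distance from peak midpoint to the nearest TSS."""
    ann = catalog.annotation
    if ann is None:
        raise ValueError("catalog lacks gene models")
    genes = ann.genes
    tss_by_chrom = {
        c: (sub["tss"].to_numpy(), sub["strand"].to_numpy(),
            sub["gene_id"].to_numpy())
        for c, sub in genes.groupby("chrom")
    }
    rows = []
    for i, p in enumerate(peaks):
        label = "intergenic"
        for feat in FEATURE_PRIORITY:
            if _overlaps_any(p.chrom, p.start, p.end, catalog.features[feat]):
                label = feat
                break
        mid = (p.start + p.end) // 2
        dist = np.nan
        gene_id = ""
        entry = tss_by_chrom.get(p.chrom)
        if entry is not None:
            tss, strand, ids = entry
            j = int(np.argmin(np.abs(tss - mid)))
            raw = mid - int(tss[j])
            dist = -raw if strand[j] == "-" else raw
            gene_id = str(ids[j])
        rows.append(
            dict(
                name=f"peak{i + 1}", chrom=p.chrom, start=p.start, end=p.end,
                feature=label, tss_distance=dist, nearest_gene=gene_id,
            )
        )
    return pd.DataFrame(rows)


def feature_fold_enrichment(
    peaks: Sequence[GenomicInterval],
    feature: Sequence[GenomicInterval],
    genome_size: int,
) -> float:
    """overlap_bp * genome_size / (peak_bp * feature_bp), merged sets."""
    peak_bp = total_bp(peaks)
    feature_bp = total_bp(feature)
    if peak_bp == 0 or feature_bp == 0:
        raise ValueError("peak and feature sets must be nonempty")
    return overlap_bp(peaks, feature) * genome_size / (peak_bp * feature_bp)


def pairwise_set_enrichment(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> float:
    """overlap_bp / (setA_bp * setB_bp), merged sets; symmetric."""
    bp_a = total_bp(set_a)
    bp_b = total_bp(set_b)
    if bp_a == 0 or bp_b == 0:
        raise ValueError("both sets must be nonempty")
    return overlap_bp(set_a, set_b) / (bp_a * bp_b)


def enrichment_matrix(
    row_sets: Mapping[str, Sequence[GenomicInterval]],
    col_sets: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            col: [
                pairwise_set_enrichment(row_sets[r], col_sets[col])
                for r in row_sets
            ]
            for col in col_sets
        },
        index=list(row_sets),
    )


def zscale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores for heatmap display (mean 0, sd 1)."""
    out = matrix.astype(float).copy()
    for col in out.columns:
        v = out[col].to_numpy()
        sd = v.std(ddof=0)
        out[col] = 0.0 if sd == 0 else (v - v.mean()) / sd
    return out


def fraction_covered(
    reference: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> float:
    """Fraction of reference elements (count-wise) hit by >=1 bp of peak."""
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    per: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        per.setdefault(p.chrom, []).append((p.start, p.end))
    hit = 0
    for r in reference:
        for s, e in per.get(r.chrom, ()):
            if s < r.end and e > r.start:
                hit += 1
                break
    return hit / len(reference)


def tss_profile(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    window: int = 10000,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Histogram of peak midpoints by signed distance to nearest TSS."""
    if window <= 0:
        raise ValueError("window must be positive")
    tss_by_chrom = {
        c: (sub["tss"].to_numpy(), sub["strand"].to_numpy())
        for c, sub in annotation.genes.groupby("chrom")
    }
    dists = []
    for p in peaks:
        entry = tss_by_chrom.get(p.chrom)
        if entry is None:
            continue
        tss, strand = entry
        mid = (p.start + p.end) // 2
        j = int(np.argmin(np.abs(tss - mid)))
        raw = mid - int(tss[j])
        d = -raw if strand[j] == "-" else raw
        if -window <= d <= window:
            dists.append(d)
    edges = np.arange(-window, window + bin_size, bin_size)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
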