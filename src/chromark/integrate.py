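"""Combinatorial marking classification, expression integration,
correlation, MDS clustering and distal-element-to-gene linkage."""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeAnnotation, GenomicInterval
from .peaks import PeakSet, QuantMatrix

__all__ = [
    "build_marking_table",
    "venn_counts",
    "assign_groups",
    "expression_by_group",
    "mann_whitney",
    "correlate",
    "mds_embed",
    "link_dels_to_genes",
    "top_ranked_dels",
]

ACTIVE_GROUPS = {
    "group1": frozenset({"H3K18la", "H3K27ac", "H3K4me3"}),
    "group2": frozenset({"H3K27ac", "H3K4me3"}),
    "group3": frozenset({"H3K4me3"}),
}

# combined sample size below which the Mann-Whitney U distribution is
# enumerated exactly rather than normal-approximated
EXACT_MW_MAX_N = 24


def build_marking_table(
    elements: pd.DataFrame | Sequence[GenomicInterval],
    peaksets: Mapping[str, PeakSet],
) -> pd.DataFrame:
    """Element x mark boolean table by >= 1 bp peak intersection.

    ``elements`` needs chrom/start/end/name columns; extra columns
    (element_class, gene_id, ...) are carried through.
    """
    if not isinstance(elements, pd.DataFrame):
        elements = pd.DataFrame(
            {
                "chrom": [e.chrom for e in elements],
                "start": [e.start for e in elements],
                "end": [e.end for e in elements],
                "name": [
                    e.name if e.name else f"el{i + 1}"
                    for i, e in enumerate(elements)
                ],
            }
        )
    out = elements.reset_index(drop=True).copy()
    for mark, ps in peaksets.items():
        per: dict[str, list[tuple[int, int]]] = {}
        for p in ps:
            per.setdefault(p.chrom, []).append((p.start, p.end))
        hits = np.zeros(len(out), dtype=bool)
        for i, row in enumerate(out.itertuples(index=False)):
            for s, e in per.get(row.chrom, ()):
                if s < row.end and e > row.start:
                    hits[i] = True
                    break
        out[mark] = hits
    return out


def venn_counts(
    marking: pd.DataFrame, marks: Sequence[str]
) -> pd.DataFrame:
    """Counts and fractions of actively-marked elements per Venn cell.

    Cells are labeled by '+'-joined mark names; fractions are over
    elements carrying at least one of ``marks``.
    """
    flags = marking[list(marks)].to_numpy(dtype=bool)
    active = flags.any(axis=1)
    n_active = int(active.sum())
    rows = []
    for r in range(1, len(marks) + 1):
        for combo in itertools.combinations(marks, r):
            cell = np.ones(len(marking), dtype=bool)
            for m in marks:
                col = marking[m].to_numpy(dtype=bool)
                cell &= col if m in combo else ~col
            n = int(cell.sum())
            rows.append(
                dict(
                    cell="+".join(combo),
                    n_marks=r,
                    count=n,
                    fraction=n / n_active if n_active else 0.0,
                )
            )
    return pd.DataFrame(rows)


def assign_groups(
    marking: pd.DataFrame,
    group_defs: Mapping[str, frozenset] = ACTIVE_GROUPS,
) -> pd.DataFrame:
    """Map each actively marked element to its exact mark-combination
    group; combinations outside the named groups keep an explicit
    '+'-joined label."""
    marks = sorted({m for s in group_defs.values() for m in s})
    flags = marking[marks]
    combo_to_name = {v: k for k, v in group_defs.items()}
    labels = []
    for _, row in flags.iterrows():
        present = frozenset(m for m in marks if row[m])
        if not present:
            labels.append("unmarked")
        else:
            labels.append(combo_to_name.get(present, "+".join(sorted(present))))
    out = marking.copy()
    out["group"] = labels
    return out


def mann_whitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value; exact when the combined sample
    is small (<= 24 observations, no ties), else normal approximation
    with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # degenerate: no information against the null
    has_ties = len(np.unique(pooled)) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= EXACT_MW_MAX_N and not has_ties) \
        else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def expression_by_group(
    grouped: pd.DataFrame,
    expression: pd.DataFrame,
    value_col: str = "log2RPKM",
    gene_col: str = "gene_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group expression summaries and pairwise Mann-Whitney tests.

    ``grouped`` maps gene_id -> group (from :func:`assign_groups`),
    ``expression`` maps gene_id -> ``value_col``.
    """
    merged = grouped[[gene_col, "group"]].merge(
        expression[[gene_col, value_col]], on=gene_col
    )
    stats_rows = []
    values: dict[str, np.ndarray] = {}
    for group, sub in merged.groupby("group"):
        v = sub[value_col].to_numpy()
        values[group] = v
        stats_rows.append(
            dict(
                group=group, n=len(v), median=float(np.median(v)),
                mean=float(v.mean()),
            )
        )
    test_rows = []
    for a, b in itertools.combinations(sorted(values), 2):
        test_rows.append(
            dict(
                group_a=a, group_b=b,
                p_value=mann_whitney(values[a], values[b]),
            )
        )
    return pd.DataFrame(stats_rows), pd.DataFrame(test_rows)


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson (mark vs mark) or Spearman (mark vs expression)
    correlation with two-sided p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def mds_embed(
    matrix: QuantMatrix | pd.DataFrame, top_features: int = 500
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples.

    Pairwise distance = root-mean-square of the ``top_features`` largest
    absolute differences between two samples' (log) columns, computed
    per pair.  Sign convention: first sample's first coordinate >= 0.
    """
    counts = matrix.counts if isinstance(matrix, QuantMatrix) else matrix
    samples = list(counts.columns)
    n = len(samples)
    if n < 2:
        raise ValueError("need >= 2 samples")
    V = counts.to_numpy(dtype=float)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(V[:, i] - V[:, j])
            k = min(top_features, len(diff))
            top = np.partition(diff, len(diff) - k)[len(diff) - k:]
            D[i, j] = D[j, i] = float(np.sqrt(np.mean(top**2)))
    # double centering
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    dims = min(2, n - 1)
    coords = U[:, :dims] * np.sqrt(np.maximum(w[:dims], 0.0))
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(n)])
    for d in range(2):
        if coords[0, d] < 0:
            coords[:, d] = -coords[:, d]
    return pd.DataFrame(coords, columns=["dim1", "dim2"], index=samples)


def link_dels_to_genes(
    dels: pd.DataFrame | Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Link each dELS to the nearest non-overlapping protein-coding-gene
    promoter (edge-to-edge distance; ties break to the smaller promoter
    start, then the lexicographically smaller gene id)."""
    if not isinstance(dels, pd.DataFrame):
        dels = pd.DataFrame(
            {
                "chrom": [d.chrom for d in dels],
                "start": [d.start for d in dels],
                "end": [d.end for d in dels],
                "name": [
                    d.name if d.name else f"dels{i + 1}"
                    for i, d in enumerate(dels)
                ],
            }
        )
    prom = annotation.promoters()
    coding = annotation.genes.loc[
        annotation.genes["biotype"] == "protein_coding", "gene_id"
    ]
    prom = prom[prom["gene_id"].isin(set(coding))]
    rows = []
    for d in dels.itertuples(index=False):
        cand = prom[prom["chrom"] == d.chrom]
        best = None
        for p in cand.itertuples(index=False):
            if p.start < d.end and p.end > d.start:
                continue  # overlapping promoters are excluded
            if p.end <= d.start:
                dist = int(d.start - p.end)
            else:
                dist = int(p.start - d.end)
            key = (dist, p.start, p.gene_id)
            if best is None or key < best[0]:
                best = (key, p.gene_id, dist)
        rows.append(
            dict(
                dels=d.name,
                gene_id=best[1] if best else "",
                distance=best[2] if best else np.nan,
            )
        )
    return pd.DataFrame(rows)


def top_ranked_dels(
    quant: QuantMatrix,
    links: pd.DataFrame,
    sample: str,
    n: int = 2000,
) -> pd.DataFrame:
    """Genes linked to the ``n`` highest-signal dELS, deduplicated
    keeping the best rank; equal signals order by coordinate."""
    regions = quant.regions.copy()
    regions["signal"] = quant.counts[sample].to_numpy()
    regions = regions.sort_values(
        ["signal", "chrom", "start"], ascending=[False, True, True],
        kind="stable",
    )
    if n > len(regions):
        n = len(regions)
    top = regions.head(n).merge(
        links, left_on="name", right_on="dels", how="left"
    )
    top = top[top["gene_id"].notna() & (top["gene_id"] != "")]
    top = top.drop_duplicates(subset="gene_id", keep="first")
    return top[["name", "chrom", "start", "end", "signal", "gene_id"]].reset_index(
        drop=True
    )
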