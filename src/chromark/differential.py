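"""Pairwise differential marking / expression between two conditions.

Counts over a shared union-region frame are compared with an exact
conditional count test: library sizes are equalized, condition sums are
tested against a 50:50 split of their total — binomial when the
common dispersion (method-of-moments across regions) is <= 0, else a
negative-binomial two-sided "minimum likelihood" exact test.  Fold
changes use CPM means with a pseudocount of 0.5, which makes the
statistic exactly antisymmetric under condition swap.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .integrate import mann_whitney
from .peaks import QuantMatrix

__all__ = [
    "bh_adjust",
    "differential_regions",
    "diff_change_correlation",
    "fc_by_elementclass",
    "expression_shift_by_peakclass",
]

PSEUDOCOUNT = 0.5
DEFAULT_FDR = 0.05
DEFAULT_MIN_LFC = 0.5
STRICT_MIN_LFC = 1.5  # used for the per-cCRE-class significant-region sets
_EXACT_TOTAL_CAP = 100_000


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _moment_dispersion(groups: Sequence[np.ndarray]) -> float:
    """Common NB dispersion phi from var = mu + phi * mu^2, pooled over
    regions using within-condition means/variances only (so planted
    between-condition differences do not inflate the estimate).
    Conditions with a single replicate contribute nothing."""
    num = den = 0.0
    for scaled in groups:
        if scaled.shape[1] < 2:
            continue
        mu = scaled.mean(axis=1)
        var = scaled.var(axis=1, ddof=1)
        ok = mu > 0
        num += (var[ok] - mu[ok]).sum()
        den += (mu[ok] ** 2).sum()
    return float(num / den) if den > 0 else 0.0


def _exact_count_p(a: float, b: float, phi: float) -> float:
    """Two-sided exact p for split (a, b) of total t = a + b under the
    null that both condition sums share mean t/2.

    Poisson route (phi <= 0): conditional binomial(t, 1/2), minlike
    two-sided.  NB route: P(A=x, B=t-x) for A,B iid NB(mu=t/2, phi);
    p = sum of point probabilities <= that of the observed split.
    """
    a, b = int(round(a)), int(round(b))
    t = a + b
    if t == 0:
        return 1.0
    if t > _EXACT_TOTAL_CAP:
        # normal fallback for huge totals
        mu = t / 2.0
        var = mu + max(phi, 0.0) * mu**2
        z = (a - mu) / np.sqrt(2 * var)
        return float(2 * stats.norm.sf(abs(z)))
    if phi <= 1e-8:  # moment estimate at/below Poisson
        return float(stats.binomtest(a, t, 0.5).pvalue)
    mu = t / 2.0
    size = 1.0 / phi  # NB 'r'; var = mu + mu^2/size
    prob = size / (size + mu)
    x = np.arange(t + 1)
    logp = stats.nbinom.logpmf(x, size, prob) + stats.nbinom.logpmf(
        t - x, size, prob
    )
    p_obs = logp[a]
    tot = np.logaddexp.reduce(logp)
    keep = logp <= p_obs + 1e-12
    return float(np.exp(np.logaddexp.reduce(logp[keep]) - tot))


def differential_regions(
    quant_a: QuantMatrix,
    quant_b: QuantMatrix,
    fdr: float = DEFAULT_FDR,
    min_abs_lfc: float = DEFAULT_MIN_LFC,
) -> pd.DataFrame:
    """Per-region differential table between two conditions.

    Both matrices must be raw counts over the identical region frame
    (the pair-specific union peak list). Columns of the result: region
    name/coordinates, per-condition CPM means, log2FC, p, FDR and a
    significance flag at the given thresholds.
    """
    if quant_a.normalization != "raw" or quant_b.normalization != "raw":
        raise ValueError("differential test expects raw count matrices")
    ra, rb = quant_a.regions, quant_b.regions
    if not (
        len(ra) == len(rb)
        and (ra["name"].to_numpy() == rb["name"].to_numpy()).all()
    ):
        raise ValueError("region frames differ between conditions")

    A = quant_a.counts.to_numpy(dtype=float)
    B = quant_b.counts.to_numpy(dtype=float)
    lib_a = np.array([quant_a.library_sizes[s] for s in quant_a.counts.columns])
    lib_b = np.array([quant_b.library_sizes[s] for s in quant_b.counts.columns])
    if (lib_a <= 0).any() or (lib_b <= 0).any():
        raise ValueError("zero library size")

    # equalize library sizes to the overall mean before testing
    ref = float(np.concatenate([lib_a, lib_b]).mean())
    A_s = A * (ref / lib_a)[None, :]
    B_s = B * (ref / lib_b)[None, :]
    phi = _moment_dispersion([A_s, B_s])

    cpm_a = (A * (1e6 / lib_a)[None, :]).mean(axis=1)
    cpm_b = (B * (1e6 / lib_b)[None, :]).mean(axis=1)
    lfc = np.log2(cpm_a + PSEUDOCOUNT) - np.log2(cpm_b + PSEUDOCOUNT)

    # sums of equalized counts, rescaled so each condition contributes
    # comparably regardless of replicate number
    n_a, n_b = A.shape[1], B.shape[1]
    tot_a = A_s.sum(axis=1) * (1.0 if n_a == n_b else n_b / n_a)
    tot_b = B_s.sum(axis=1)
    pvals = np.array(
        [_exact_count_p(a, b, phi) for a, b in zip(tot_a, tot_b)]
    )
    fdr_vals = bh_adjust(pvals)
    out = ra.copy()
    out["mean_cpm_a"] = cpm_a
    out["mean_cpm_b"] = cpm_b
    out["log2fc"] = lfc
    out["p_value"] = pvals
    out["fdr"] = fdr_vals
    out["significant"] = (fdr_vals < fdr) & (np.abs(lfc) > min_abs_lfc)
    out.attrs["dispersion"] = phi
    return out


def diff_change_correlation(
    diff_marks: pd.DataFrame,
    diff_expr: pd.DataFrame,
    links: pd.DataFrame | None = None,
    fdr: float = DEFAULT_FDR,
    min_abs_lfc: float = DEFAULT_MIN_LFC,
    expr_fdr_filter: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of mark log2FC vs expression log2FC on
    matched elements passing the filters.

    Marks side: FDR < ``fdr`` and |log2FC| > ``min_abs_lfc``; expression
    side: |log2FC| > ``min_abs_lfc`` (FDR filter optional).  ``links``
    maps the marks table's region names to gene ids (columns
    ``dels``/``gene_id``); omit it when the marks table already carries
    a ``gene_id`` column (promoter mode).
    """
    marks = diff_marks[
        (diff_marks["fdr"] < fdr)
        & (diff_marks["log2fc"].abs() > min_abs_lfc)
    ].copy()
    if links is not None:
        marks = marks.merge(
            links[["dels", "gene_id"]], left_on="name", right_on="dels"
        )
    if "gene_id" not in marks.columns:
        raise ValueError("marks table lacks gene ids and no links given")
    expr = diff_expr[diff_expr["log2fc"].abs() > min_abs_lfc]
    if expr_fdr_filter:
        expr = expr[expr["fdr"] < fdr]
    merged = marks.merge(
        expr[["name", "log2fc"]].rename(
            columns={"name": "gene_id", "log2fc": "expr_log2fc"}
        ),
        on="gene_id",
    )
    if len(merged) < 3:
        raise ValueError("fewer than 3 matched pairs after filtering")
    r, p = stats.pearsonr(merged["log2fc"], merged["expr_log2fc"])
    scatter = merged[["name", "gene_id", "log2fc", "expr_log2fc"]]
    return float(r), float(p), scatter.reset_index(drop=True)


def fc_by_elementclass(
    diff: pd.DataFrame,
    classes: Mapping[str, str],
    fdr: float = DEFAULT_FDR,
    strict_lfc: float = STRICT_MIN_LFC,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """|log2FC| distributions per element class + pairwise tests, plus
    the subset of strongly significant regions (FDR and |log2FC| >
    ``strict_lfc``) per class."""
    d = diff.copy()
    d["element_class"] = d["name"].map(lambda n: classes.get(n, "other"))
    dist_rows, values = [], {}
    for cls, sub in d.groupby("element_class"):
        v = sub["log2fc"].abs().to_numpy()
        values[cls] = v
        dist_rows.append(
            dict(element_class=cls, n=len(v), median_abs_lfc=float(np.median(v)),
                 mean_abs_lfc=float(v.mean()))
        )
    test_rows = []
    if len(values) > 1:
        for a, b in itertools.combinations(sorted(values), 2):
            test_rows.append(
                dict(class_a=a, class_b=b,
                     p_value=mann_whitney(values[a], values[b]))
            )
    sig = d[(d["fdr"] < fdr) & (d["log2fc"].abs() > strict_lfc)]
    sig_counts = (
        sig.groupby("element_class").size().rename("n_significant").reset_index()
    )
    return (
        pd.DataFrame(dist_rows),
        pd.DataFrame(test_rows, columns=["class_a", "class_b", "p_value"]),
        sig_counts,
    )


def expression_shift_by_peakclass(
    diff_expr: pd.DataFrame,
    peak_presence: Mapping[str, str],
    nominal_p: float = 0.01,
    min_abs_lfc: float = DEFAULT_MIN_LFC,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Treatment expression shifts grouped by promoter-peak presence
    class ({condition A only, condition B only, both, none}).

    Returns per-class distributions, pairwise Mann-Whitney p-values and
    the genes passing nominal p < ``nominal_p`` and |log2FC| >
    ``min_abs_lfc`` with their class.
    """
    d = diff_expr.copy()
    d["peak_class"] = d["name"].map(lambda g: peak_presence.get(g, "none"))
    dist_rows, values = [], {}
    for cls, sub in d.groupby("peak_class"):
        v = sub["log2fc"].to_numpy()
        values[cls] = v
        dist_rows.append(
            dict(peak_class=cls, n=len(v), median_lfc=float(np.median(v)),
                 mean_lfc=float(v.mean()))
        )
    test_rows = []
    if len(values) > 1:
        for a, b in itertools.combinations(sorted(values), 2):
            test_rows.append(
                dict(class_a=a, class_b=b,
                     p_value=mann_whitney(values[a], values[b]))
            )
    hits = d[
        (d["p_value"] < nominal_p) & (d["log2fc"].abs() > min_abs_lfc)
    ][["name", "log2fc", "p_value", "peak_class"]]
    return (
        pd.DataFrame(dist_rows),
        pd.DataFrame(test_rows, columns=["class_a", "class_b", "p_value"]),
        hits.reset_index(drop=True),
    )
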