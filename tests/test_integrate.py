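import numpy as np
import pandas as pd
import pytest

from chromark.integrate import (
    assign_groups,
    build_marking_table,
    correlate,
    expression_by_group,
    link_dels_to_genes,
    mann_whitney,
    mds_embed,
    top_ranked_dels,
    venn_counts,
)
from chromark.io_formats import GenomicInterval
from chromark.peaks import Peak, PeakSet, QuantMatrix


def _peakset(coords):
    return PeakSet(
        [Peak(c, s, e, 1.0, 1.0, (s + e) // 2) for c, s, e in coords]
    )


class TestMarkingTable:
    def _elements(self):
        return [
            GenomicInterval("chr1", 0, 100, name="P1"),
            GenomicInterval("chr1", 1000, 1100, name="P2"),
            GenomicInterval("chr1", 2000, 2100, name="P3"),
        ]

    def test_enumerated_cells(self):
        peaksets = {
            "A": _peakset([("chr1", 50, 60), ("chr1", 1050, 1060)]),
            "B": _peakset([("chr1", 1050, 1060)]),
            "C": _peakset([("chr1", 1050, 1060), ("chr1", 2050, 2060)]),
        }
        marking = build_marking_table(self._elements(), peaksets)
        cells = venn_counts(marking, ["A", "B", "C"]).set_index("cell")
        assert cells.loc["A", "count"] == 1
        assert cells.loc["A+B+C", "count"] == 1
        assert cells.loc["C", "count"] == 1
        others = cells.drop(["A", "A+B+C", "C"])
        assert (others["count"] == 0).all()

    def test_no_peaks_empty_active(self):
        peaksets = {"A": _peakset([("chr2", 0, 10)])}
        marking = build_marking_table(self._elements(), peaksets)
        assert not marking["A"].any()

    def test_cells_partition_active_elements(self):
        rng = np.random.default_rng(0)
        elements = [
            GenomicInterval("chr1", i * 500, i * 500 + 100, name=f"E{i}")
            for i in range(30)
        ]
        peaksets = {
            m: _peakset(
                [
                    ("chr1", i * 500 + 20, i * 500 + 40)
                    for i in range(30)
                    if rng.random() < 0.5
                ]
            )
            for m in ("A", "B")
        }
        marking = build_marking_table(elements, peaksets)
        cells = venn_counts(marking, ["A", "B"])
        n_active = int((marking[["A", "B"]].any(axis=1)).sum())
        assert cells["count"].sum() == n_active
        if n_active:
            assert cells["fraction"].sum() == pytest.approx(1.0)


class TestGroups:
    def test_named_groups(self):
        marking = pd.DataFrame(
            {
                "name": ["a", "b", "c", "d", "e"],
                "H3K18la": [True, False, False, True, False],
                "H3K27ac": [True, True, False, False, False],
                "H3K4me3": [True, True, True, False, False],
            }
        )
        out = assign_groups(marking)
        assert list(out["group"]) == [
            "group1", "group2", "group3", "H3K18la", "unmarked"
        ]


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        # all 3 low vs all 3 high: U=0 in 1 of C(6,3)=20 splits,
        # two-sided doubles -> 0.1
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_equal_p_one(self):
        assert mann_whitney([2, 2, 2], [2, 2, 2]) == 1.0

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        p = mann_whitney(x, y)
        assert p < 1e-10

    def test_empty_group(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestExpressionByGroup:
    def test_planted_ordering(self):
        rng = np.random.default_rng(5)
        genes, groups, values = [], [], []
        means = {"group1": 8.0, "group2": 6.0, "group3": 4.0}
        for g, mu in means.items():
            for i in range(40):
                genes.append(f"{g}_{i}")
                groups.append(g)
                values.append(rng.normal(mu, 1.0))
        grouped = pd.DataFrame({"gene_id": genes, "group": groups})
        expr = pd.DataFrame({"gene_id": genes, "log2RPKM": values})
        stats_df, tests_df = expression_by_group(grouped, expr)
        med = stats_df.set_index("group")["median"]
        assert med["group1"] > med["group2"] > med["group3"]
        assert (tests_df["p_value"] < 0.05).all()

    def test_empty_group_error(self):
        grouped = pd.DataFrame({"gene_id": ["g1"], "group": ["group1"]})
        expr = pd.DataFrame({"gene_id": ["g2"], "log2RPKM": [1.0]})
        with pytest.raises(Exception):
            stats_df, tests_df = expression_by_group(grouped, expr)
            if len(stats_df) == 0:
                raise ValueError("no overlap")


class TestCorrelate:
    def test_spearman_monotone_invariance(self):
        x = np.linspace(0, 3, 20)
        r, _ = correlate(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)

    def test_pearson_self(self):
        x = np.arange(10, dtype=float)
        r, p = correlate(x, x, method="pearson")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_bivariate_normal_sampling_bound(self):
        rng = np.random.default_rng(11)
        n, rho = 2000, 0.5
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        r, _ = correlate(x, y, method="pearson")
        assert 0.45 <= r <= 0.55

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_short_input_error(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])


class TestMdsEmbed:
    def _matrix(self, cols):
        df = pd.DataFrame(cols)
        return df

    def test_two_samples_exact_distance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=600)
        b = a + rng.normal(size=600)
        df = pd.DataFrame({"s1": a, "s2": b})
        coords = mds_embed(df, top_features=500)
        diff = np.abs(a - b)
        top = np.sort(diff)[-500:]
        expected = float(np.sqrt(np.mean(top**2)))
        got = np.linalg.norm(coords.loc["s1"] - coords.loc["s2"])
        assert got == pytest.approx(expected, rel=1e-9)

    def test_duplicate_sample_zero_distance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        df = pd.DataFrame({"s1": a, "s2": a, "s3": a + 5})
        coords = mds_embed(df, top_features=50)
        assert np.allclose(coords.loc["s1"], coords.loc["s2"], atol=1e-6)

    def test_three_samples_euclidean_recovery(self):
        # three feature vectors whose top-RMS distances are mutually
        # Euclidean-realizable: 2-D embedding must reproduce them
        rng = np.random.default_rng(2)
        m = 40
        cols = {f"s{i}": rng.normal(size=m) for i in range(3)}
        df = pd.DataFrame(cols)
        coords = mds_embed(df, top_features=m)
        V = df.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                want = np.sqrt(np.mean((V[:, i] - V[:, j]) ** 2))
                got = np.linalg.norm(
                    coords.iloc[i].to_numpy() - coords.iloc[j].to_numpy()
                )
                assert got == pytest.approx(want, abs=1e-6)

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 4)),
                          columns=list("abcd"))
        coords = mds_embed(df, top_features=50)
        assert coords.iloc[0, 0] >= 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            mds_embed(pd.DataFrame({"s1": [1.0, 2.0]}))

    def test_replicates_cluster(self, small_config, small_dataset):
        # replicate pairs must sit closer than any cross-sample pair
        from chromark.peaks import normalize, quantify

        tracks = {
            f"{t}_rep{r + 1}": small_dataset.tracks[("H3K18la", t, r)]
            for t in small_config.tissues
            for r in range(2)
        }
        qm = quantify(tracks, tile=3000)
        qm = normalize(qm, "log2CPM")
        coords = mds_embed(qm, top_features=500)
        d = {
            (a, b): np.linalg.norm(coords.loc[a] - coords.loc[b])
            for a in coords.index
            for b in coords.index
            if a < b
        }
        for t in small_config.tissues:
            same = d[(f"{t}_rep1", f"{t}_rep2")]
            cross = [
                v for (a, b), v in d.items()
                if (a.startswith(t)) != (b.startswith(t))
            ]
            assert same < min(cross)


class TestLinkDels:
    def test_nearest_promoter(self, toy_annotation):
        dels = [GenomicInterval("chr1", 20_000, 20_500, name="d1")]
        links = link_dels_to_genes(dels, toy_annotation)
        # promoter gA = [8000,12000), gB = [58000,62000)
        assert links["gene_id"].iloc[0] == "gA"
        assert links["distance"].iloc[0] == 20_000 - 12_000

    def test_overlapping_promoter_excluded(self, toy_annotation):
        # inside gA's promoter window -> must link to gB
        dels = [GenomicInterval("chr1", 11_000, 11_400, name="d1")]
        links = link_dels_to_genes(dels, toy_annotation)
        assert links["gene_id"].iloc[0] == "gB"

    def test_distance_tie_break(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["gB", "gA"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "+"],
                "tss": [30_000, 10_000],
                "gene_start": [30_000, 10_000],
                "gene_end": [32_000, 12_000],
                "length": [2_000, 2_000],
                "biotype": ["protein_coding", "protein_coding"],
                "housekeeping": [False, False],
            }
        )
        from chromark.io_formats import GenomeAnnotation

        ann = GenomeAnnotation(
            genes=genes, cgi=pd.DataFrame(columns=["chrom", "start", "end"]),
            chrom_sizes={"chr1": 100_000},
        )
        # promoters end at 12000 and start at 28000; dELS equidistant
        dels = [GenomicInterval("chr1", 19_000, 21_000, name="d1")]
        links = link_dels_to_genes(dels, ann)
        # tie at 7000 bp: smaller promoter start wins -> gA
        assert links["gene_id"].iloc[0] == "gA"

    def test_no_eligible_gene(self, toy_annotation):
        dels = [GenomicInterval("chr9", 0, 100, name="d1")]
        links = link_dels_to_genes(dels, toy_annotation)
        assert links["gene_id"].iloc[0] == ""
        assert np.isnan(links["distance"].iloc[0])


class TestTopRankedDels:
    def _quant(self, signals):
        n = len(signals)
        regions = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": [i * 1000 for i in range(n)],
                "end": [i * 1000 + 500 for i in range(n)],
                "name": [f"d{i}" for i in range(n)],
            }
        )
        counts = pd.DataFrame({"s": list(signals)},
                              index=regions["name"].to_numpy())
        return QuantMatrix(regions, counts, {"s": float(sum(signals))})

    def _links(self, n):
        return pd.DataFrame(
            {"dels": [f"d{i}" for i in range(n)],
             "gene_id": [f"g{i}" for i in range(n)],
             "distance": [100] * n}
        )

    def test_top_one(self):
        qm = self._quant([5.0, 50.0, 1.0])
        out = top_ranked_dels(qm, self._links(3), "s", n=1)
        assert list(out["gene_id"]) == ["g1"]

    def test_ties_order_by_coordinate(self):
        qm = self._quant([3.0, 3.0, 3.0])
        out = top_ranked_dels(qm, self._links(3), "s", n=2)
        assert list(out["name"]) == ["d0", "d1"]

    def test_n_larger_than_available(self):
        qm = self._quant([1.0, 2.0])
        out = top_ranked_dels(qm, self._links(2), "s", n=10)
        assert len(out) == 2

    def test_dedup_keeps_best_rank(self):
        qm = self._quant([5.0, 50.0, 1.0])
        links = self._links(3)
        links.loc[2, "gene_id"] = "g1"  # d2 links to same gene as d1
        out = top_ranked_dels(qm, links, "s", n=3)
        assert list(out["gene_id"]) == ["g1", "g0"]


class TestCgiRestrictedCorrelation:
    def test_cgi_correlation_stronger_when_noise_at_noncgi(self):
        # planted link everywhere, extra noise only at non-CGI promoters
        rng = np.random.default_rng(13)
        n = 400
        cgi = rng.random(n) < 0.5
        intensity = rng.random(n) * 4
        expr = 2.0 * intensity + rng.normal(0, 0.3, n)
        expr[~cgi] += rng.normal(0, 3.0, (~cgi).sum())
        r_all, _ = correlate(intensity, expr, method="spearman")
        r_cgi, _ = correlate(intensity[cgi], expr[cgi], method="spearman")
        assert r_cgi >= r_all
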