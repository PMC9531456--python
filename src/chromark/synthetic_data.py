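"""Toy multi-tissue genome + coverage + expression generator.

Plants a known promoter/enhancer occupancy structure — CGI and non-CGI
active promoters, poised promoters, shared and tissue-specific distal
enhancer-like elements (dELS), proximal elements (pELS) — and emits
per-(mark, tissue, replicate) coverage tracks plus expression tables
whose log-mean is linearly coupled to the planted promoter marking.
Ground truth is returned alongside for recovery tests.

Signal model: Poisson per 25-bp micro-bin with mean ``background_rate``,
multiplied by ``enrichment_fold`` inside elements whose planted
(mark, class, tissue) occupancy indicator is 1, then run-length encoded
into bedGraph intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, SignalTrack, write_bedgraph

__all__ = [
    "ELEMENT_CLASSES",
    "OccupancyTable",
    "SyntheticConfig",
    "TruthTables",
    "default_occupancy",
    "generate_genome",
    "sample_occupancy",
    "simulate_coverage",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]

PROMOTER_HALFWIDTH = 2000

ELEMENT_CLASSES = (
    "CGI_promoter_active",
    "nonCGI_promoter_active",
    "promoter_poised",
    "dELS_shared",
    "dELS_tissue_specific",
    "pELS",
    "none",
)

# weight of each active mark in the planted promoter activity score that
# drives expression; H3K18la dominates so that la+ac+me3 > ac+me3 > me3
_ACTIVITY_WEIGHTS = {"H3K18la": 1.0, "H3K27ac": 0.5, "H3K4me3": 0.25}


class OccupancyTable:
    """(mark, element_class, tissue_class) -> occupancy probability.

    ``tissue_class`` is ``"matching"`` (the element's own tissue, or every
    tissue for classes without an owner) or ``"other"``.  Missing entries
    default to 0.
    """

    def __init__(self, entries: dict[tuple[str, str, str], float]):
        for (mark, cls, tc), p in entries.items():
            if cls not in ELEMENT_CLASSES:
                raise ValueError(f"unknown element class {cls!r}")
            if tc not in ("matching", "other"):
                raise ValueError(f"unknown tissue class {tc!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy p={p} outside [0,1]")
        if entries.get(("H3K18la", "dELS_tissue_specific", "other"), 0.0) > 0:
            raise ValueError(
                "H3K18la occupancy at tissue-specific dELS must be zero "
                "for non-matching tissues"
            )
        self.entries = dict(entries)

    def prob(self, mark: str, element_class: str, matching: bool) -> float:
        tc = "matching" if matching else "other"
        return self.entries.get((mark, element_class, tc), 0.0)

    def marks(self) -> list[str]:
        return sorted({m for m, _, _ in self.entries})


def default_occupancy(marks: list[str] | None = None) -> OccupancyTable:
    """Occupancy defaults mirroring the qualitative structure the
    pipeline is meant to recover: active promoters carry H3K4me3+H3K27ac
    (CGI ones usually also H3K18la), poised promoters carry
    H3K4me3+H3K27me3, dELS carry H3K27ac+H3K18la, and tissue-specific
    dELS only in their own tissue."""
    entries = {
        ("H3K4me3", "CGI_promoter_active", "matching"): 0.97,
        ("H3K27ac", "CGI_promoter_active", "matching"): 0.90,
        ("H3K18la", "CGI_promoter_active", "matching"): 0.85,
        ("H3K4me3", "nonCGI_promoter_active", "matching"): 0.95,
        ("H3K27ac", "nonCGI_promoter_active", "matching"): 0.70,
        ("H3K18la", "nonCGI_promoter_active", "matching"): 0.25,
        ("H3K4me3", "promoter_poised", "matching"): 0.90,
        ("H3K27me3", "promoter_poised", "matching"): 0.90,
        ("H3K27ac", "dELS_shared", "matching"): 0.90,
        ("H3K18la", "dELS_shared", "matching"): 0.85,
        ("H3K27ac", "dELS_tissue_specific", "matching"): 0.95,
        ("H3K18la", "dELS_tissue_specific", "matching"): 0.95,
        ("H3K27ac", "pELS", "matching"): 0.85,
        ("H3K18la", "pELS", "matching"): 0.45,
        ("H3K4me3", "pELS", "matching"): 0.30,
    }
    if marks is not None:
        entries = {k: v for k, v in entries.items() if k[0] in marks}
    return OccupancyTable(entries)


@dataclass
class SyntheticConfig:
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 60
    frac_housekeeping: float = 0.3
    n_tissues: int = 3
    marks: list[str] = field(
        default_factory=lambda: ["H3K18la", "H3K27ac", "H3K4me3", "H3K27me3"]
    )
    occupancy: OccupancyTable | None = None
    background_rate: float = 0.5  # expected counts per 25-bp micro-bin
    enrichment_fold: float = 10.0
    expression_noise_sd: float = 0.5  # log2 units
    seed: int = 0
    # layout / extras
    n_dels_shared: int = 12
    n_dels_specific: int = 24
    frac_pels: float = 0.4
    frac_cgi_nonhk: float = 0.3  # non-housekeeping genes with active CGI promoter
    frac_poised: float = 0.2
    micro_bin: int = 25
    n_replicates: int = 2
    expression_base: float = 4.0  # log2 counts at zero planted activity
    expression_slope: float = 2.0
    element_halfwidth: int = 500  # dELS/pELS half-width

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = default_occupancy(self.marks)
        for attr in ("n_chroms", "chrom_length", "n_genes", "n_tissues",
                     "micro_bin", "n_replicates"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("frac_housekeeping", "frac_pels", "frac_cgi_nonhk",
                     "frac_poised"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise ValueError(f"{attr} must lie in [0,1]")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


@dataclass
class TruthTables:
    """Planted ground truth: element coordinates + classes, per-element
    per-mark per-tissue occupancy indicators, per-gene activity scores."""

    elements: pd.DataFrame  # chrom,start,end,name,element_class,owner_tissue,gene_id
    occupancy: pd.DataFrame  # name,element_class,mark,tissue,occupied
    gene_truth: pd.DataFrame  # gene_id,tissue,promoter_la,promoter_activity
    hmm_path: pd.DataFrame | None = None


# ---------------------------------------------------------------------------


def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def generate_genome(
    config: SyntheticConfig,
) -> tuple[GenomeAnnotation, TruthTables]:
    """Lay out gene models, CGIs and regulatory elements on a toy genome.

    dELS are placed strictly more than 2000 bp from every TSS, pELS within
    [200, 2000] bp and PLS within 200 bp; violating layouts (chromosome
    too short) raise instead of silently clipping.
    """
    rng = _rng(config, 1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    genes_per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    slot = config.chrom_length // genes_per_chrom
    if slot < 30_000:
        raise ValueError(
            f"chromosome too short: {genes_per_chrom} genes need slots of "
            f">=30000 bp, got {slot}"
        )

    n_hk = int(round(config.frac_housekeeping * config.n_genes))
    hk_idx = set(
        rng.choice(config.n_genes, size=n_hk, replace=False).tolist()
    )

    gene_rows, cgi_rows, element_rows = [], [], []
    total_dels = config.n_dels_shared + config.n_dels_specific
    dels_placed = 0
    tissue_cycle = 0

    gi = 0
    for chrom in chroms:
        for s in range(genes_per_chrom):
            if gi >= config.n_genes:
                break
            slot_start = s * slot
            tss = slot_start + 5000 + int(rng.integers(0, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(2000, 8000))
            if strand == "+":
                g_start, g_end = tss, tss + glen
            else:
                g_start, g_end = tss - glen, tss
            gene_id = f"gene{gi + 1:04d}"
            hk = gi in hk_idx

            if hk:
                pclass = "CGI_promoter_active"
            else:
                u = rng.random()
                if u < config.frac_cgi_nonhk:
                    pclass = "CGI_promoter_active"
                elif u < config.frac_cgi_nonhk + config.frac_poised:
                    pclass = "promoter_poised"
                else:
                    pclass = "nonCGI_promoter_active"

            gene_rows.append(
                dict(
                    gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                    gene_start=g_start, gene_end=g_end, length=glen,
                    biotype="protein_coding", housekeeping=hk,
                )
            )
            if pclass in ("CGI_promoter_active",) or (
                pclass == "promoter_poised" and rng.random() < 0.5
            ):
                cgi_rows.append(
                    dict(chrom=chrom, start=max(tss - 300, 0), end=tss + 500)
                )
            element_rows.append(
                dict(
                    chrom=chrom,
                    start=max(tss - PROMOTER_HALFWIDTH, 0),
                    end=min(tss + PROMOTER_HALFWIDTH, config.chrom_length),
                    name=f"prom_{gene_id}",
                    element_class=pclass,
                    owner_tissue="",
                    gene_id=gene_id,
                )
            )
            # pELS downstream-agnostic: centered 200-2000 bp from TSS
            if rng.random() < config.frac_pels:
                off = int(rng.integers(400, 1500))
                side = 1 if rng.random() < 0.5 else -1
                center = tss + side * off
                half = min(config.element_halfwidth, 300)
                p_start, p_end = center - half, center + half
                element_rows.append(
                    dict(
                        chrom=chrom, start=p_start, end=p_end,
                        name=f"pels_{gene_id}", element_class="pELS",
                        owner_tissue="", gene_id=gene_id,
                    )
                )
            # distal elements live in the back half of the slot
            if dels_placed < total_dels:
                zone_lo = slot_start + 15_000
                zone_hi = slot_start + slot - 8_000
                center = int(rng.integers(zone_lo, zone_hi))
                d_start = center - config.element_halfwidth
                d_end = center + config.element_halfwidth
                if dels_placed < config.n_dels_shared:
                    cls, owner = "dELS_shared", ""
                else:
                    cls = "dELS_tissue_specific"
                    owner = config.tissues[tissue_cycle % config.n_tissues]
                    tissue_cycle += 1
                element_rows.append(
                    dict(
                        chrom=chrom, start=d_start, end=d_end,
                        name=f"dels{dels_placed + 1:04d}", element_class=cls,
                        owner_tissue=owner, gene_id="",
                    )
                )
                dels_placed += 1
            gi += 1
    if dels_placed < total_dels:
        raise ValueError(
            f"could not place {total_dels} dELS in {config.n_genes} gene "
            "slots; increase n_genes or chromosome count"
        )

    genes = pd.DataFrame(gene_rows)
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    elements = pd.DataFrame(element_rows)

    # enforce the distance-class contract
    dels = elements[elements["element_class"].str.startswith("dELS")]
    for row in dels.itertuples(index=False):
        same = genes[genes["chrom"] == row.chrom]
        d = np.minimum(
            np.abs(same["tss"].to_numpy() - row.start),
            np.abs(same["tss"].to_numpy() - (row.end - 1)),
        )
        inside = (same["tss"].to_numpy() >= row.start) & (
            same["tss"].to_numpy() < row.end
        )
        if np.any(inside) or d.min() <= 2000:
            raise ValueError(
                f"dELS {row.name} violates the >2000 bp TSS distance rule"
            )

    annotation = GenomeAnnotation(
        genes=genes, cgi=cgi, chrom_sizes=chrom_sizes,
        elements={"planted": elements},
    )
    occupancy = sample_occupancy(elements, config)
    gene_truth = _gene_truth(elements, occupancy, config)
    truth = TruthTables(
        elements=elements, occupancy=occupancy, gene_truth=gene_truth
    )
    return annotation, truth


def sample_occupancy(
    elements: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Draw planted occupancy indicators.

    Classes without an owner tissue get one Bernoulli draw shared by all
    tissues (so housekeeping promoter marking is concordant across
    tissues); tissue-specific classes draw per tissue with the
    matching/other probability split.
    """
    rng = _rng(config, 2)
    occ = config.occupancy
    rows = []
    for el in elements.itertuples(index=False):
        for mark in config.marks:
            if el.owner_tissue:
                for tissue in config.tissues:
                    p = occ.prob(
                        mark, el.element_class, matching=tissue == el.owner_tissue
                    )
                    rows.append(
                        dict(
                            name=el.name, element_class=el.element_class,
                            mark=mark, tissue=tissue,
                            occupied=bool(rng.random() < p),
                        )
                    )
            else:
                p = occ.prob(mark, el.element_class, matching=True)
                hit = bool(rng.random() < p)
                for tissue in config.tissues:
                    rows.append(
                        dict(
                            name=el.name, element_class=el.element_class,
                            mark=mark, tissue=tissue, occupied=hit,
                        )
                    )
    return pd.DataFrame(rows)


def _gene_truth(
    elements: pd.DataFrame, occupancy: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    prom = elements[elements["element_class"].str.contains("promoter")]
    occ = occupancy.set_index(["name", "mark", "tissue"])["occupied"]
    rows = []
    for el in prom.itertuples(index=False):
        for tissue in config.tissues:
            la = 0.0
            activity = 0.0
            for mark, w in _ACTIVITY_WEIGHTS.items():
                if mark not in config.marks:
                    continue
                hit = float(occ.get((el.name, mark, tissue), False))
                activity += w * hit
                if mark == "H3K18la":
                    la = hit
            rows.append(
                dict(
                    gene_id=el.gene_id, tissue=tissue,
                    promoter_la=la, promoter_activity=activity,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def simulate_coverage(
    annotation: GenomeAnnotation,
    truth: TruthTables,
    mark: str,
    tissue: str,
    config: SyntheticConfig,
    replicate: int = 0,
) -> SignalTrack:
    """Poisson micro-bin coverage with planted element enrichment."""
    if mark not in config.marks:
        raise ValueError(f"unknown mark {mark!r}")
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    mi, ti = config.marks.index(mark), config.tissues.index(tissue)
    rng = _rng(config, 3, mi, ti, replicate)

    occ = truth.occupancy
    hot = occ[(occ["mark"] == mark) & (occ["tissue"] == tissue) & occ["occupied"]]
    hot_names = set(hot["name"])
    hot_elements = truth.elements[truth.elements["name"].isin(hot_names)]

    mb = config.micro_bin
    data = {}
    for chrom, size in annotation.chrom_sizes.items():
        n_bins = -(-size // mb)
        lam = np.full(n_bins, config.background_rate, dtype=np.float64)
        sub = hot_elements[hot_elements["chrom"] == chrom]
        for el in sub.itertuples(index=False):
            b0 = el.start // mb
            b1 = -(-el.end // mb)
            lam[b0:b1] = config.background_rate * config.enrichment_fold
            if config.background_rate == 0:
                # zero-background degenerate case still shows the element
                lam[b0:b1] = config.enrichment_fold
        counts = rng.poisson(lam).astype(np.float64)
        starts, ends, values = _run_length_encode(counts, mb, size)
        data[chrom] = (starts, ends, values)
    return SignalTrack(data, chrom_sizes=annotation.chrom_sizes)


def _run_length_encode(
    counts: np.ndarray, bin_width: int, chrom_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(counts) == 0:
        z = np.array([], dtype=np.int64)
        return z, z.copy(), np.array([], dtype=np.float64)
    change = np.flatnonzero(np.diff(counts)) + 1
    starts_bin = np.concatenate(([0], change))
    ends_bin = np.concatenate((change, [len(counts)]))
    starts = starts_bin * bin_width
    ends = np.minimum(ends_bin * bin_width, chrom_size)
    values = counts[starts_bin]
    return starts.astype(np.int64), ends.astype(np.int64), values


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: TruthTables,
    tissue: str,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Per-gene expression with log2 mean = base + slope * planted
    promoter activity (+ Gaussian noise). Columns: gene_id, count,
    length, tissue."""
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    ti = config.tissues.index(tissue)
    rng = _rng(config, 4, ti)
    gt = truth.gene_truth
    sub = gt[gt["tissue"] == tissue].set_index("gene_id")
    genes = annotation.genes
    activity = (
        sub.reindex(genes["gene_id"])["promoter_activity"].fillna(0.0).to_numpy()
    )
    noise = rng.normal(0.0, config.expression_noise_sd, size=len(genes))
    log2_mean = config.expression_base + config.expression_slope * activity + noise
    counts = np.power(2.0, log2_mean)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "count": counts,
            "length": genes["length"].to_numpy(),
            "tissue": tissue,
        }
    )


# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    annotation: GenomeAnnotation
    truth: TruthTables
    tracks: dict[tuple[str, str, int], SignalTrack]
    expression: dict[str, pd.DataFrame]


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    annotation, truth = generate_genome(config)
    tracks = {}
    for mark in config.marks:
        for tissue in config.tissues:
            for rep in range(config.n_replicates):
                tracks[(mark, tissue, rep)] = simulate_coverage(
                    annotation, truth, mark, tissue, config, replicate=rep
                )
    expression = {
        t: simulate_expression(annotation, truth, t, config)
        for t in config.tissues
    }
    return SyntheticDataset(config, annotation, truth, tracks, expression)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "chrom.sizes", "w") as fh:
        for c, s in ds.annotation.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    ds.annotation.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    ds.annotation.cgi.assign(name="CGI").to_csv(
        out / "cgi.bed", sep="\t", index=False, header=False
    )
    el = ds.truth.elements
    el[["chrom", "start", "end", "element_class", "name"]].to_csv(
        out / "elements.bed", sep="\t", index=False, header=False
    )
    ds.truth.elements.to_csv(out / "truth_elements.tsv", sep="\t", index=False)
    ds.truth.occupancy.to_csv(out / "truth_occupancy.tsv", sep="\t", index=False)
    ds.truth.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    for (mark, tissue, rep), track in ds.tracks.items():
        write_bedgraph(track, out / f"{tissue}_{mark}_rep{rep + 1}.bedgraph")
    for tissue, expr in ds.expression.items():
        expr.to_csv(out / f"expression_{tissue}.tsv", sep="\t", index=False)
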