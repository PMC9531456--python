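import pandas as pd
import pytest

from chromark.io_formats import GenomeAnnotation
from chromark.synthetic_data import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_chroms=2,
        chrom_length=400_000,
        n_genes=20,
        n_tissues=2,
        n_dels_shared=4,
        n_dels_specific=8,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def toy_annotation() -> GenomeAnnotation:
    """Two genes on one 100-kb chromosome, one CGI promoter."""
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tss": [10_000, 60_000],
            "gene_start": [10_000, 55_000],
            "gene_end": [15_000, 60_000],
            "length": [5_000, 5_000],
            "biotype": ["protein_coding", "protein_coding"],
            "housekeeping": [True, False],
        }
    )
    cgi = pd.DataFrame({"chrom": ["chr1"], "start": [9_800], "end": [10_300]})
    return GenomeAnnotation(genes=genes, cgi=cgi, chrom_sizes={"chr1": 100_000})
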