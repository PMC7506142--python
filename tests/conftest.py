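import numpy as np
import pytest

from transinteract import BindingSite, SiteCatalog, UtrModel, pool_sites


def make_utr(gene_id: str, length: int, sequence: str | None = None,
             strand: str = "+", start: int = 0) -> UtrModel:
    return UtrModel(
        gene_id=gene_id, transcript_id=f"T-{gene_id}", strand=strand,
        blocks=((start, start + length),), chrom="chr1", sequence=sequence,
    )


@pytest.fixture
def two_site_catalog() -> SiteCatalog:
    """One gene, one site from each of two RBPs, overlapping by 1 nt."""
    utrs = {"G1": make_utr("G1", 100)}
    sites = [
        BindingSite("RBP1", "RBP", "G1", 5, 15),
        BindingSite("RBP2", "RBP", "G1", 14, 30),
    ]
    return pool_sites(utrs, sites)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
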