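import numpy as np
import pandas as pd
import pytest

from exodna.count_io import GeneCatalog, SampleCoverageTable


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    """Six genes, three depths, hand-written so expectations are checkable."""
    genes = pd.Index(["g1", "g2", "g3", "g4", "g5", "g6"], name="gene_id")
    ann = pd.DataFrame(
        {
            "domain": ["bacteria", "bacteria", "virus", "archaea", "unknown", "eukaryote"],
            "family": ["Pelagibacteraceae", "Prochlorococcus", "Myoviridae",
                       "Nitrosopumilaceae", None, "Pelagomonadaceae"],
            "tag": [None, "HL", "host:Prochlorococcus", None, None, None],
        },
        index=genes,
    )
    cov = pd.DataFrame(
        [
            [2.0, 6.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 4.0, 4.0],
            [0.0, 0.0, 3.0],
            [0.0, 0.0, 0.0],  # zero catalog coverage at every depth
            [5.0, 1.0, 2.0],
        ],
        index=genes,
        columns=[75.0, 500.0, 1000.0],
    )
    return GeneCatalog(annotations=ann, coverage=cov)


@pytest.fixture
def tiny_sample(tiny_catalog) -> SampleCoverageTable:
    counts = pd.Series([10, 20, 30, 0, 25, 15], index=tiny_catalog.gene_ids)
    return SampleCoverageTable(
        sample_id="free_500m", fraction_type="free",
        collection_depth=500.0, counts=counts,
    )


def random_sample(catalog: GeneCatalog, seed: int,
                  read_depth: int = 10_000) -> SampleCoverageTable:
    """A sample with uniform-random counts over a catalog's genes."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(read_depth, np.full(len(catalog), 1.0 / len(catalog)))
    return SampleCoverageTable(
        sample_id=f"rand_{seed}", fraction_type="free", collection_depth=125.0,
        counts=pd.Series(counts, index=catalog.gene_ids),
    )
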