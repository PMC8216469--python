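import numpy as np
import pandas as pd
import pytest

from ligrseq import FeatureTable, SimConfig, make_ua_features

CHROM_LEN = 20_000


@pytest.fixture
def toy_annotation() -> FeatureTable:
    """Hand-traced annotation on one 20 kb chromosome.

    geneA 1001-2000(+), geneB 2101-2600(-) [100 nt gap to A],
    geneC 2621-3000(+) [20 nt gap to B], geneD 9001-9500(+) [distal],
    srna1 15001-15100(+), geneE 19500-19900(-) [wraps close to geneA on a
    circular chromosome].
    """
    df = pd.DataFrame(
        [
            ("geneA", "chr", 1001, 2000, "+", "CDS"),
            ("geneB", "chr", 2101, 2600, "-", "CDS"),
            ("geneC", "chr", 2621, 3000, "+", "CDS"),
            ("geneD", "chr", 9001, 9500, "+", "CDS"),
            ("srna1", "chr", 15001, 15100, "+", "sRNA"),
            ("geneE", "chr", 19500, 19900, "-", "CDS"),
        ],
        columns=["id", "chrom", "start", "end", "strand", "ftype"],
    )
    return FeatureTable(df)


@pytest.fixture
def toy_features(toy_annotation) -> FeatureTable:
    """Toy annotation plus UA features tiling the rest of the chromosome."""
    return make_ua_features(toy_annotation, {"chr": CHROM_LEN})


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        genome_length=30_000, n_genes=12, n_srnas=4, n_reads=2_000,
        replicate_count=2, seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
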