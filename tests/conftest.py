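import numpy as np
import pytest

from nlchrom.core import GenomicRegion, NucleosomeAnnotation
from nlchrom.chain import build_nl_chain, map_nl_to_cg
from nlchrom.synth import NucleosomeArraySpec, SyntheticMapSpec, gen_hic, gen_nucleosomes


@pytest.fixture(scope="session")
def region20k():
    return GenomicRegion("chrS", 0, 20_000)


@pytest.fixture(scope="session")
def phased_annotation(region20k):
    return gen_nucleosomes(
        NucleosomeArraySpec(region=region20k, nrl=200, jitter_sd=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def nl_chain(phased_annotation):
    return map_nl_to_cg(build_nl_chain(phased_annotation), 5000)


@pytest.fixture(scope="session")
def block_map_40():
    """Balanced 40-bin map with two planted junctions (3 blocks)."""
    return gen_hic(
        SyntheticMapSpec(
            n_bins=40,
            block_boundaries=(14, 27),
            block_enrichment=4.0,
            alpha=1.0,
            noise_cv=0.05,
            seed=1,
        )
    )
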