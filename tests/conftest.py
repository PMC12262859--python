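import numpy as np
import pandas as pd
import pytest

from xenofrag.genome import generate_reference
from xenofrag.synth import (
    CohortDesign,
    default_graft_spec,
    default_host_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_genomes():
    """Small host (3 acrocentric chroms) + graft (2 p/q chroms) references."""
    host = generate_reference(default_host_spec(300_000, 3), 101)
    graft = generate_reference(default_graft_spec(300_000, 2), 102)
    return host, graft


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(fragments_per_sample=20_000, cna_bin_size=50_000)


@pytest.fixture(scope="session")
def small_cohort(small_design, small_genomes):
    host, graft = small_genomes
    return generate_cohort(small_design, host, graft, 42)


@pytest.fixture(scope="session")
def noiseless_cohort(small_design, small_genomes):
    host, graft = small_genomes
    return generate_cohort(small_design.noiseless(), host, graft, 43)


def toy_fragments(lengths, chrom="c1", start=1000, mapq=60):
    """Fragment table from a list of lengths, all placed at one start."""
    lengths = np.asarray(lengths, dtype=np.int64)
    return pd.DataFrame(
        {
            "read_id": np.arange(lengths.size),
            "chrom": chrom,
            "start": start,
            "end": start + lengths,
            "length": lengths,
            "mapq": mapq,
        }
    )
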