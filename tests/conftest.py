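import numpy as np
import pytest

from snvgmhi.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort shared by read-only tests."""
    cfg = SimConfig(n_healthy=12, n_nonhealthy=12, n_genomes=12,
                    genome_len=6000, seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_cds(small_cohort):
    """Coding-strand sequence of every gene in the small cohort."""
    comp = str.maketrans("ACGT", "TGCA")
    out = {}
    for ann in small_cohort.annotations:
        seq = small_cohort.genomes[ann.genome_id][ann.start:ann.end]
        if ann.strand == "-":
            seq = seq.translate(comp)[::-1]
        out[ann.gene_id] = seq
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
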