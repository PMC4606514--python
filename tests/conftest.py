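import numpy as np
import pytest
from hypothesis import settings

import bayesbpi as b

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def tiny_genotype_file(tmp_path):
    """3 individuals x 2 markers, codes [[0,1],[2,1],[1,2]]."""
    path = tmp_path / "geno.tsv"
    path.write_text("id\tm1\tm2\nA\t0\t1\nB\t2\t1\nC\t1\t2\n")
    return path


@pytest.fixture(scope="session")
def mfp_dataset():
    """Small major-QTL trait: one locus at 30% of the genetic variance."""
    return b.simulate_dataset(b.preset("mfp", 300, 400, seed=42))


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-noise phenotype over HWE genotypes."""
    spec = b.ArchitectureSpec(n_individuals=200, n_markers=150, n_qtl=0, seed=7)
    return b.simulate_dataset(spec)
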