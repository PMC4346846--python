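import numpy as np
import pytest

from cga.simulate import genotype_table_from_joint, paper_fixture


@pytest.fixture(scope="session")
def study_counts():
    """The packaged in-study counts: (joint table, per-locus, diplotype sizes)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def study_joint(study_counts):
    return study_counts[0]


@pytest.fixture(scope="session")
def study_genotypes(study_joint):
    """Individual-level genotype table expanded from the joint counts."""
    return genotype_table_from_joint(study_joint)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
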