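import numpy as np
import pytest

from ivypop.popdata import HaplotypeAlignment
from ivypop.simulate import generate_dataset, study_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def four_hap_alignment():
    """The hand-computable 4-haplotype alignment {AA, AT, TA, TT}."""
    seqs = np.array([list("AA"), list("AT"), list("TA"), list("TT")])
    return HaplotypeAlignment("toy", seqs, ["i1", "i1", "i2", "i2"])


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down island-model dataset shared by io/pipeline tests."""
    cfg = study_preset(seed=11, n_populations=6, lines_per_population=5,
                       n_loci=3, theta_per_site=2e-4)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def preset_dataset():
    """One full-size study-system dataset (24 pops x 8 lines, 7 loci)."""
    return generate_dataset(study_preset(seed=4))
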