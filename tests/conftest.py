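import numpy as np
import pytest

from gwtraj import (
    VisitDesign,
    generate_cohort,
    make_kl_truth,
    make_paper_like_truth,
)


@pytest.fixture(scope="session")
def kl_truth():
    """Three-component recovery truth with sigma = 1 and no reporting bias."""
    return make_kl_truth()


@pytest.fixture(scope="session")
def full_design():
    """Visit design with every visit observed (5 records per subject)."""
    return VisitDesign(p_miss_A=0.0, p_miss_B=0.0, p_miss_C=0.0, p_late_recruit=0.0)


@pytest.fixture(scope="session")
def small_cohort(kl_truth, full_design):
    return generate_cohort(kl_truth, full_design, 200, seed=11)


@pytest.fixture(scope="session")
def paper_truth():
    return make_paper_like_truth()
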