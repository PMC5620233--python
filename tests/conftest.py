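import numpy as np
import pytest

from ctcseq.simulate import CohortConfig, generate_cohort
from ctcseq.wga_errors import build_blacklist, call_amplification_errors


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (48 patients, 14 amplified normals)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_error_sets(default_cohort):
    return [
        call_amplification_errors(p.amplified_normal, p.normal)
        for p in default_cohort.amplified_normal_patients
    ]


@pytest.fixture(scope="session")
def default_blacklist(default_error_sets):
    return build_blacklist(default_error_sets, min_recurrence=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
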