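import pytest

import resectability as rs
from resectability.cohort import Assessor


@pytest.fixture(scope="session")
def full_cohort():
    """Deterministic 279-record example cohort (published-margin reconstruction)."""
    return rs.example_cohort()


@pytest.fixture(scope="session")
def analysis_cohort(full_cohort):
    cohort, _ = rs.apply_eligibility(full_cohort)
    return cohort


@pytest.fixture(scope="session")
def operable_cohort(analysis_cohort):
    return rs.exclude_inoperable(analysis_cohort)


@pytest.fixture(scope="session")
def complete_case_cohort(operable_cohort):
    return rs.complete_case_subset(
        operable_cohort, [Assessor.US, Assessor.CT, Assessor.WB_DWI_MRI]
    )


@pytest.fixture(scope="session")
def fixture_csv(tmp_path_factory, full_cohort):
    path = tmp_path_factory.mktemp("data") / "example_cohort.csv"
    rs.write_cohort(full_cohort, path)
    return path
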