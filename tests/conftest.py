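import pytest

from biowean import CRITERIA, CoefficientSet, CriterionProfile


@pytest.fixture(scope="session")
def coeffs() -> CoefficientSet:
    """The packaged published coefficient set."""
    return CoefficientSet.default()


def make_profile(cid_months: float = 12.0, **flags) -> CriterionProfile:
    """Profile with the named flags set to 1 and the rest 0."""
    values = {name: 0 for name in CRITERIA}
    for name, value in flags.items():
        assert name in CRITERIA, name
        values[name] = value
    return CriterionProfile(cid_months=cid_months, **values)


@pytest.fixture()
def zero_profile() -> CriterionProfile:
    return make_profile()


@pytest.fixture()
def ones_profile() -> CriterionProfile:
    return make_profile(**{name: 1 for name in CRITERIA})
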