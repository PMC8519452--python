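import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from homingdrive import AmpliconReference, FitnessScheme, derive_rates

#: measured transmission rates of the drive strain (F/M) and NHEJ fraction
D_F, D_M, U = 0.927, 0.913, 0.266


@pytest.fixture(scope="session")
def printed_rates():
    """Rates derived from the measured transmission data, p=0."""
    return derive_rates(D_F, D_M, U, 0.0)


@pytest.fixture(scope="session")
def observed_costs():
    return FitnessScheme.observed()


@pytest.fixture(scope="session")
def canonical_reference():
    return AmpliconReference.canonical()


@pytest.fixture()
def short_reference():
    """A 60-bp reference with the drive target site, for fast alignments."""
    left = "TTGACCGTAGCATGCCAGTA"
    right = "CCATGAGGTACGTCACC"
    seq = left + "GAACAACAACAAAAGACTGT" + "AGG" + right
    return AmpliconReference(seq, len(left))
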