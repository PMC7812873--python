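import pytest

from sgpartition import PartitionCurve, paper_calibrated_curve


@pytest.fixture(scope="session")
def calibrated_curve() -> PartitionCurve:
    """Power law through the printed tethering medians (14% at x=2, 62% at x=27)."""
    return paper_calibrated_curve()


@pytest.fixture()
def exact_curve() -> PartitionCurve:
    """A clean curve with round parameters for exact-recovery tests."""
    return PartitionCurve(c=10.0, p=0.5, n=2)
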