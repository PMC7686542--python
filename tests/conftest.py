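import numpy as np
import pytest

from gcflow import NetworkPartition, SubjectRecord, default_partition


@pytest.fixture(scope="session")
def partition() -> NetworkPartition:
    return default_partition()


@pytest.fixture
def toy_partition() -> NetworkPartition:
    """Four ROIs in two subsystems: a, b in MTL; c, d in DAN."""
    return NetworkPartition(
        ("a", "b", "c", "d"),
        {"a": "MTL", "b": "MTL", "c": "DAN", "d": "DAN"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


def make_record(data: np.ndarray, subject_id: str = "s1", group: str = "NC", tr: float = 2.0) -> SubjectRecord:
    return SubjectRecord(subject_id=subject_id, group=group, data=data, tr_seconds=tr)
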