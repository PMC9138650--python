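import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phyloepi import AlignedSeqSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy3() -> AlignedSeqSet:
    """Three taxa, two CpG sites: column 1 conserved, column 5 altered in s2."""
    return AlignedSeqSet(("s1", "s2", "s3"), ("ACGTACGT", "ACGTATGT", "ACGTACGT"))


def random_alignment(
    rng: np.random.Generator,
    n_taxa: int,
    length: int,
    gap_prob: float = 0.0,
) -> AlignedSeqSet:
    """Random alignment used by oracle-equivalence tests."""
    alphabet = np.array(list("ACGT"))
    rows = []
    for _ in range(n_taxa):
        chars = alphabet[rng.integers(0, 4, size=length)]
        if gap_prob > 0:
            gaps = rng.random(length) < gap_prob
            chars = np.where(gaps, np.array(["-"]), chars)
        rows.append("".join(chars))
    labels = tuple(f"t{i}" for i in range(n_taxa))
    return AlignedSeqSet(labels, tuple(rows))
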