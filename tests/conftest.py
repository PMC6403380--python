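import numpy as np
import pytest
from hypothesis import settings

from mdums.core import AA_INDEX, DomainRecord, UnfoldingMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_domain(sequence: str, start: int = 1, protein_id: str = "P1",
                domain_type: str = "other", ordinal: int = 1) -> DomainRecord:
    return DomainRecord(
        protein_id=protein_id, domain_type=domain_type, ordinal=ordinal,
        start=start, end=start + len(sequence) - 1, sequence=sequence,
    )


def make_matrix(domain: DomainRecord, fill: float = 0.5,
                identity: float | None = 0.5) -> UnfoldingMatrix:
    """Uniform matrix; identity cells set separately (None leaves them at fill)."""
    values = np.full((domain.length, 20), fill)
    if identity is not None:
        for i, aa in enumerate(domain.sequence):
            values[i, AA_INDEX[aa]] = identity
    return UnfoldingMatrix(domain=domain, values=values)


@pytest.fixture
def simple_domain():
    return make_domain("ACDE")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
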