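import numpy as np
import pytest

import hetdr as hd


@pytest.fixture(scope="session")
def planted_network() -> hd.HeterogeneousNetwork:
    """Default planted-cluster synthetic network (sparsity 0.95)."""
    return hd.generate_synthetic(hd.SyntheticSpec(seed=3))


@pytest.fixture
def tiny_network() -> hd.HeterogeneousNetwork:
    """Handmade 4-drug / 3-disease network."""
    m_rr = np.array(
        [
            [1.0, 0.8, 0.1, 0.2],
            [0.8, 1.0, 0.3, 0.1],
            [0.1, 0.3, 1.0, 0.5],
            [0.2, 0.1, 0.5, 1.0],
        ]
    )
    m_dd = np.array(
        [
            [1.0, 0.6, 0.2],
            [0.6, 1.0, 0.4],
            [0.2, 0.4, 1.0],
        ]
    )
    m_rd = np.array(
        [
            [1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return hd.HeterogeneousNetwork(
        drug_ids=["r1", "r2", "r3", "r4"],
        disease_ids=["d1", "d2", "d3"],
        M_rr=m_rr,
        M_dd=m_dd,
        M_rd=m_rd,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_network(seed: int, n: int = 12, m: int = 9) -> hd.HeterogeneousNetwork:
    """Small random valid network for round-trip / property tests."""
    r = np.random.default_rng(seed)
    a = r.random((n, n))
    m_rr = (a + a.T) / 2
    np.fill_diagonal(m_rr, 1.0)
    b = r.random((m, m))
    m_dd = (b + b.T) / 2
    np.fill_diagonal(m_dd, 1.0)
    m_rd = (r.random((n, m)) < 0.3).astype(float)
    m_rd[0, 0] = 1.0  # at least one association
    return hd.HeterogeneousNetwork(
        drug_ids=[f"r{i}" for i in range(n)],
        disease_ids=[f"d{j}" for j in range(m)],
        M_rr=m_rr,
        M_dd=m_dd,
        M_rd=m_rd,
    )
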