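import numpy as np
import pytest

from adtargets.biodomain import TermSystem
from adtargets.harmonize import DrugTargetGraph
from adtargets.synthetic_data import DegreeLaw, SimConfig


@pytest.fixture
def toy_graph() -> DrugTargetGraph:
    """4 drugs, 6 edges, 5 genes; gene g2 targeted twice."""
    return DrugTargetGraph([
        ("dA", "g1"), ("dA", "g2"),
        ("dB", "g2"), ("dB", "g3"),
        ("dC", "g4"),
        ("dD", "g5"),
    ])


@pytest.fixture
def toy_terms() -> dict[str, frozenset]:
    return {
        "t1": frozenset({"g1", "g2"}),
        "t2": frozenset({"g2", "g3", "g4"}),
        "t3": frozenset({"g5"}),
    }


@pytest.fixture
def toy_term_system(toy_terms) -> TermSystem:
    return TermSystem(
        dict(toy_terms),
        domain_of={"t1": "BD01", "t2": "BD01", "t3": "BD02"},
        subdomain_of={"t1": "BD01.s1", "t2": "BD01.s2", "t3": "BD02.s1"},
    )


@pytest.fixture
def small_cfg() -> SimConfig:
    return SimConfig(
        seed=42, n_drugs=40, n_genes=300,
        drug_degree_law=DegreeLaw("zipf", {"a": 2.0, "max_degree": 20}),
        n_domains=3, terms_per_domain=5, term_size_range=(10, 40),
        n_trials_per_source=20,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
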