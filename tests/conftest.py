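import numpy as np
import pandas as pd
import pytest

from crcsig.expression import ExpressionMatrix
from crcsig.signatures import GeneSignature, SignatureRegistry
from crcsig.simulate import SyntheticCohortConfig, simulate_cohort


@pytest.fixture
def gene_matrix():
    """Gene-level toy matrix: 3 genes x 2 samples."""
    values = pd.DataFrame(
        {"A": [2.0, 4.0, 10.0], "B": [1.0, 3.0, 8.0]},
        index=["G1", "G2", "G3"],
    )
    return ExpressionMatrix(values=values, feature_kind="gene")


@pytest.fixture
def probe_matrix():
    """Probe-level toy: G1 has two probes, G2 one."""
    values = pd.DataFrame(
        {"A": [1.0, 3.0, 5.0], "B": [2.0, 2.0, 2.0]},
        index=["p1", "p2", "p3"],
    )
    return ExpressionMatrix(
        values=values,
        feature_kind="probe",
        probe_to_gene={"p1": "G1", "p2": "G1", "p3": "G2"},
    )


@pytest.fixture
def dasa_six_gene():
    return GeneSignature(
        name="DASAS6",
        up_genes=frozenset({"EPHA2", "CAV1", "CAV2", "ANXA1", "PTRF"}),
        down_genes=frozenset({"IGFBP2"}),
        source="six-gene dasatinib sensitivity",
    )


@pytest.fixture
def multi_component_registry(dasa_six_gene):
    reg = SignatureRegistry()
    reg.add(dasa_six_gene)
    reg.add(
        GeneSignature(
            name="SRC",
            up_genes=frozenset(f"U{i}" for i in range(5)),
            down_genes=frozenset(f"D{i}" for i in range(3)),
            plus_inf_genes=frozenset(f"P{i}" for i in range(2)),
            minus_inf_genes=frozenset(f"M{i}" for i in range(2)),
            source="composite",
        )
    )
    reg.add(GeneSignature(name="MEK18", up_genes=frozenset(f"K{i}" for i in range(18))))
    return reg


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure synthetic cohort, small enough for fast tests."""
    return simulate_cohort(SyntheticCohortConfig(n_samples=150, seed=7))


@pytest.fixture(scope="session")
def noise_cohort():
    """No planted class structure anywhere: every sample is pure noise."""
    cfg = SyntheticCohortConfig(
        n_samples=150,
        seed=13,
        marker_effect=0.0,
        class_latent_shifts={k: {} for k in ("CMS1", "CMS2", "CMS3", "CMS4", "NOISE")},
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
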