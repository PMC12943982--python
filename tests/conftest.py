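import numpy as np
import pytest

from saltreg.dataset import Dataset, DesignMatrix, PhenotypeRecord, Term
from saltreg.simulate import SyntheticConfig, generate

EQ2_TERMS = [Term.parse(s) for s in ("X2", "X4", "X1^2", "X2^2", "X4^2")]


def random_dataset(rng: np.random.Generator, n: int = 20) -> Dataset:
    """Small random phenotype table for generic linear-algebra checks."""
    spad = rng.uniform(10, 50, n)
    gs = rng.uniform(10, 90, n)
    na = rng.uniform(0, 400, n)
    k = rng.uniform(10, 300, n)
    y = rng.uniform(0.1, 3.0, n)
    return Dataset(
        PhenotypeRecord(i, "G", 0.0, spad[i], gs[i], na[i], k[i], y[i]) for i in range(n)
    )


def random_design(rng: np.random.Generator, n: int, p: int) -> DesignMatrix:
    """Generic (non-phenotype) design matrix with synthetic term labels."""
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    terms = [Term("linear", (1,)), Term("square", (1,)), Term("linear", (2,)),
             Term("square", (2,)), Term("linear", (3,)), Term("cross", (1, 2)),
             Term("cross", (1, 3)), Term("square", (3,))][:p]
    return DesignMatrix(X, terms, y, list(range(n)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def eq2_terms() -> list[Term]:
    return list(EQ2_TERMS)


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-condition synthetic table shared across tests."""
    return generate(SyntheticConfig(seed=0))
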