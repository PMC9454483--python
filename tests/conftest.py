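import numpy as np
import pytest

from crcpanel.matrix import ExpressionMatrix, GeneAnnotation
from crcpanel.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic study-sized cohort (66 tumours / 10 normals, seed 1)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def toy_matrix(values, hk_rows=(), classes=None, scale="raw_counts"):
    """Small hand-built ExpressionMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [
        GeneAnnotation(f"G{i}", f"NM_{i:06d}", is_housekeeping=i in hk_rows)
        for i in range(n_genes)
    ]
    samples = [f"S{j}" for j in range(n_samples)]
    if classes is None:
        classes = ["tumour"] * n_samples
    return ExpressionMatrix(
        values=values, genes=genes, samples=samples, sample_class=list(classes),
        scale=scale,
    )


@pytest.fixture()
def censored_sample(rng):
    """Generic right-censored survival sample (n=80)."""
    t = rng.exponential(20, 80)
    c = rng.uniform(0, 40, 80)
    return np.minimum(t, c), t <= c
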