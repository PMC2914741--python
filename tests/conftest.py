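import numpy as np
import pandas as pd
import pytest

from areqtl import ExpressionMatrix, SimConfig
from areqtl.data import are_training_sites
from areqtl.motif import build_pwm
from areqtl.simulate import simulate_cohort, simulate_expression, simulate_genotypes


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=40, seed=11)


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def study(small_config, cohort):
    """(genotypes, expression, truth) for the default small study."""
    geno, _ = simulate_genotypes(small_config, cohort)
    expr, truth = simulate_expression(small_config, geno, cohort)
    return geno, expr, truth


@pytest.fixture(scope="session")
def are_pwm():
    return build_pwm(are_training_sites())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def toy_expression(values, probes=None, samples=None, detection=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=probes, columns=samples)
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, dtype=bool), index=probes,
                           columns=samples)
    return ExpressionMatrix(vals, det)
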