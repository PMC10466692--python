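import numpy as np
import pytest

import cfscreen as cf
from cfscreen.pipeline import ScreeningPipeline


@pytest.fixture(scope="session")
def genome():
    return cf.SyntheticGenome()


@pytest.fixture(scope="session")
def panel_cohort(genome):
    """Euploid reference cohort (mixed fetal sex, varied ff and GC slope)."""
    return cf.simulate_cohort(50, {}, seed=42, genome=genome)


@pytest.fixture(scope="session")
def pipeline(genome, panel_cohort):
    pipe = ScreeningPipeline(genome)
    return pipe.fit([(b, p) for b, p, _ in panel_cohort], seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
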