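import numpy as np
import pandas as pd
import pytest

from agetx import synthetic as syn


@pytest.fixture(scope="session")
def small_models():
    return syn.make_gene_models(40, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_models):
    return syn.make_genome(small_models, seed=12)


@pytest.fixture(scope="session")
def design():
    return syn.make_design()


@pytest.fixture(scope="session")
def timecourse_sim(design):
    """2000-gene time course with 10% regulated genes at the default study
    conditions (NB dispersion 0.1, amplitudes >= 1.5, 3 reps x 5 ages)."""
    genes = [f"g{i:05d}" for i in range(2000)]
    plans = syn.make_trajectory_plans(genes, frac_regulated=0.1, seed=101)
    cm, truth = syn.simulate_timecourse_counts(plans, design, seed=102)
    return cm, truth


def toy_counts(values, samples=None):
    values = np.asarray(values)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                        columns=samples)
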