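import pytest

from dualomics import DualOmicsExperiment, PipelineConfig, SimConfig
from dualomics.io import load_table1
from dualomics.simulate import simulate_experiment


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated experiment at the study's default conditions."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(default_dataset):
    """Full pipeline fit on the default dataset (screen over all genes)."""
    exp = DualOmicsExperiment.from_dataset(default_dataset)
    return exp.fit(PipelineConfig(screen_pool="all"))


@pytest.fixture(scope="session")
def table1():
    """The packaged 36-gene fold-change table."""
    return load_table1()


#: Genes the association/screen analysis singled out as key regulators.
HIGHLIGHTED = {"TUBB2", "PXG4", "PLDα2", "PFK4", "4CL1"}


@pytest.fixture(scope="session")
def highlighted_genes():
    return set(HIGHLIGHTED)
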