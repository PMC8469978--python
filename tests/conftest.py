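import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from opbias.models import ConcResponseSeries, Ligand, ReceptorConstruct
from opbias.simulate import SimulationConfig

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def m2_fused():
    return ReceptorConstruct("M2", "fused", "IPx")


@pytest.fixture
def config():
    """Default study conditions with a fixed seed."""
    return SimulationConfig(rng_seed=1)


@pytest.fixture
def noisefree_config():
    return SimulationConfig(rng_seed=1, functional_cv=0.0, binding_cv=0.0,
                            basal_fraction_range=(0.025, 0.025))


@pytest.fixture
def make_series():
    def _make(concentrations, responses, construct=None, ligand="test",
              experiment_id="exp1"):
        return ConcResponseSeries(
            construct=construct or ReceptorConstruct("M2", "fused", "IPx"),
            ligand=Ligand(ligand), concentrations=np.asarray(concentrations),
            responses=np.asarray(responses), experiment_id=experiment_id)

    return _make
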