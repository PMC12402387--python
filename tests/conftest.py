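import pytest

from psmcea import ModelRunner, gen_master_config
from psmcea.uncertainty import ParamSpec


@pytest.fixture(scope="session")
def master_config():
    return gen_master_config(42)


@pytest.fixture(scope="session")
def truth_runner(master_config):
    """Model runner bound to the synthetic ground-truth survival curves."""
    return ModelRunner(master_config)


@pytest.fixture(scope="session")
def param_specs(master_config):
    return [ParamSpec.from_model(m) for m in master_config.param_specs]


@pytest.fixture(scope="session")
def spec_by_name(param_specs):
    return {s.name: s for s in param_specs}
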