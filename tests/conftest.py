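import pytest

import tgnkin as tk
from tgnkin.models import build_model
from tgnkin.synth import NoiseSpec, default_protocols, generate_dataset


@pytest.fixture(scope="session")
def model_a():
    return build_model("A")


@pytest.fixture(scope="session")
def model_b():
    return build_model("B")


@pytest.fixture(scope="session")
def truth_a():
    return tk.ground_truth("A")


@pytest.fixture(scope="session")
def truth_b():
    return tk.ground_truth("B")


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def protocol_map(protocols):
    return {p.pid: p for p in protocols}


@pytest.fixture(scope="session")
def dataset_a(truth_a, protocols):
    """Synthetic calibration dataset generated from the variant-A ground truth."""
    data, truth = generate_dataset("A", truth_a, protocols, NoiseSpec(seed=1))
    return data, truth


def tiny_params(model, **overrides):
    """All-negligible positive parameters with selected values overridden.

    Used to isolate single reactions: a rate of 1e-300 contributes nothing
    at double precision while respecting the positivity contract.
    """
    p = {name: 1e-300 for name in model.parameter_names}
    p.update(overrides)
    return p
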