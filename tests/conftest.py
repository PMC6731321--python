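import numpy as np
import pytest

from pactmab.generate import GeneratorSpec, NoiseModel, generate_dataset, default_truth
from pactmab.model import ModelParams
from pactmab.regimen import build_schedule


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def control_dataset():
    """Noiseless control growth curve with known (k, theta)."""
    reg = build_schedule("control")
    spec = GeneratorSpec(
        truth=ModelParams(), regimen=reg, noise=NoiseModel(scale=0.0), seed=0
    )
    ds, truth = generate_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def pac25_noiseless():
    """Noiseless paclitaxel 25 nM dataset with its generating truth."""
    reg = build_schedule("paclitaxel_only", pac_dose=25.0)
    truth = default_truth("paclitaxel_only", pac_dose=25.0)
    ds, _ = generate_dataset(
        GeneratorSpec(truth=truth, regimen=reg, noise=NoiseModel(scale=0.0), seed=1)
    )
    return ds, truth, reg
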