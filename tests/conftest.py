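import numpy as np
import pytest

from weedpath.synthetic import GeneratorConfig, generate_structural


@pytest.fixture(scope="session")
def structural_obs():
    """One default structural-mode dataset (4 groups x 15 fields)."""
    return generate_structural(GeneratorConfig(seed=7, mode="structural"))


def config_with_b(bvals, seed, n_fields=15):
    """Default structural config with the density->TFI slopes replaced,
    keeping each group's mean TFI fixed."""
    cfg = GeneratorConfig(seed=seed, mode="structural", n_fields=n_fields)
    for g, b in zip(cfg.groups, bvals):
        co = cfg.coefficients[g]
        co["alpha1"] += (co["b"] - b) * 4.6
        co["b"] = b
    return cfg
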