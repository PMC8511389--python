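import numpy as np
import pytest

import canomix as cm


@pytest.fixture(scope="session")
def climate():
    """Default synthetic season, long enough to reach stand maturity."""
    return cm.generate_climate(360, seed=1)


@pytest.fixture(scope="session")
def genotype():
    """Mid-range genotype (all five parameters at their ref-range midpoints)."""
    return cm.Genotype(h_ms=100.0, phi_b=40.0, lmax_b=21.5, gai_c=0.55, par_t=0.4)


@pytest.fixture(scope="session")
def small_pure_outputs(climate, genotype):
    """One 24-plant pure-stand simulation, shared across read-only tests."""
    plot = cm.build_pure_plot(genotype, n_plants=24, density=200.0, seed=3)
    return cm.simulate_stand(plot, climate, seed=3)


def mid_ref():
    return {"h_ms": 100.0, "phi_b": 40.0, "lmax_b": 21.5, "gai_c": 0.55, "par_t": 0.4}


def zero_diff():
    return {k: 0.0 for k in cm.PARAM_NAMES}
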