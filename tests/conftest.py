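import numpy as np
import pytest

from fpbind import AnisotropyModel, EquilibriumSystem, PlateDesign


@pytest.fixture
def anis():
    """Default anisotropy mapping: rf 0.05, rb 0.25, Q = 1."""
    return AnisotropyModel(r_free=0.05, r_bound=0.25, intensity_ratio=1.0)


@pytest.fixture
def assay_constants():
    """Package-default competitive assay constants (M)."""
    return {"protein_total": 100e-9, "probe_total": 20e-9, "probe_kd": 50e-9}


@pytest.fixture
def competitive_system(assay_constants):
    def make(inhibitor_kd, inhibitor_total=0.0):
        return EquilibriumSystem(inhibitor_kd=inhibitor_kd,
                                 inhibitor_total=inhibitor_total,
                                 **assay_constants)
    return make


@pytest.fixture
def random_systems():
    """Seeded log-uniform ternary systems spanning nM-mM concentrations."""
    rng = np.random.default_rng(0)

    def draw(n):
        for _ in range(n):
            pt, lt, it = 10.0 ** rng.uniform(-9, -3, 3)
            ka, kb = 10.0 ** rng.uniform(-9, -3, 2)
            yield EquilibriumSystem(protein_total=pt, probe_total=lt,
                                    probe_kd=ka, inhibitor_total=it,
                                    inhibitor_kd=kb)
    return draw


@pytest.fixture
def quiet_plate_design():
    """Noise-free plate with the default 10-point 3-fold dilution."""
    return PlateDesign(noise_sd=0.0, seed=0)
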