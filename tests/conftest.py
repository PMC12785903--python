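import numpy as np
import pytest

import starchkin as sk

# Two-phase kinetic parameter sets reported for waxy maize amylopectin (WMA)
# paste and its high-self-assembly-index ternary complex: per-phase rate
# constants k_i (min⁻¹), equilibrium extents C_i∞ (%) and phase end times
# (min).  These drive most kinetic fixtures.
PASTE_PHASES = [
    sk.PhaseSpec(k=7.89e-2, C_inf=89.39, t_end=120.0),
    sk.PhaseSpec(k=3.20e-2, C_inf=90.13, t_end=540.0),
]
TERNARY_PHASES = [
    sk.PhaseSpec(k=2.43e-2, C_inf=60.21, t_end=200.0),
    sk.PhaseSpec(k=1.44e-2, C_inf=61.06, t_end=540.0),
]


@pytest.fixture(scope="session")
def ternary_curve_5min() -> sk.DigestionCurve:
    """Noise-free ternary-complex curve on the uniform 5-min grid."""
    return sk.gen_digestion_curve(TERNARY_PHASES, times=sk.UNIFORM_5MIN_GRID)


@pytest.fixture(scope="session")
def paste_curve() -> sk.DigestionCurve:
    """Noise-free paste curve on the standard sampling protocol."""
    return sk.gen_digestion_curve(PASTE_PHASES, times=sk.STANDARD_TIME_GRID)


@pytest.fixture(scope="session")
def paste_stack_data():
    """Paste-like lamellar stack (d = 10.88 nm), 10% jitter, with oracle."""
    spec = sk.StackSpec(d_c_mean=5.33, d_a_mean=5.55, sigma_c=0.533, sigma_a=0.555)
    q = np.linspace(0.010, 0.60, 960)
    curve, oracle = sk.gen_lamellar_scattering(spec, q_grid=q, n_realizations=20, seed=11)
    return spec, curve, oracle


@pytest.fixture(scope="session")
def ternary_stack_data():
    """Ternary-complex-like stack (d = 3.97 nm), 10% jitter, with oracle."""
    spec = sk.StackSpec(d_c_mean=1.99, d_a_mean=1.98, sigma_c=0.199, sigma_a=0.198)
    q = np.linspace(0.010, 0.60, 960)
    curve, oracle = sk.gen_lamellar_scattering(spec, q_grid=q, n_realizations=20, seed=11)
    return spec, curve, oracle
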