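import numpy as np
import pytest

from dmsofold import (
    DscSimSpec,
    RelaxSimSpec,
    TitrationSimSpec,
    molar_to_vv,
    simulate_dsc,
    simulate_relaxation,
    simulate_titration,
)


@pytest.fixture
def molar_grid_vv():
    """12-point titration grid, 0-14 M expressed in v/v%."""
    return molar_to_vv(np.linspace(0.0, 14.0, 12))


@pytest.fixture
def noiseless_titration(molar_grid_vv):
    spec = TitrationSimSpec(noise_sd=0.0, peak_ids=("P1",),
                            dmso_grid_vv=molar_grid_vv, vanish_above_vv=None)
    return simulate_titration(spec)


@pytest.fixture
def paf_regime_relaxation():
    """50-residue synthetic at tau_c = 7.7 ns, S2 ~ N(0.87, 0.06), 2% noise."""
    return simulate_relaxation(
        RelaxSimSpec(n_residues=50, tau_c_ns=7.7, field_15N_MHz=70.966,
                     noise_sd=0.02, seed=11)
    )


@pytest.fixture
def rigid_noiseless_relaxation():
    return simulate_relaxation(
        RelaxSimSpec(n_residues=50, s2_mean=1.0, s2_sd=0.0, tau_c_ns=7.7,
                     field_15N_MHz=70.966, noise_sd=0.0)
    )


@pytest.fixture
def noiseless_dsc():
    return simulate_dsc(DscSimSpec(noise_sd=0.0))
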