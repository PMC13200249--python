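import numpy as np
import pytest

import ciss_wilson as cw
from ciss_wilson.model_builder import ModeSpec, PeierlsCoupling


@pytest.fixture(scope="session")
def benchmark_chain():
    """6-site multichannel benchmark chain: NN hopping 0.1 eV, NNN SOC
    1e-3 eV along z, degenerate on-site energies."""
    return cw.multichannel_chain(6, 0.1, 1e-3)


@pytest.fixture(scope="session")
def bridge_chain():
    """4-site single-channel bridge used in the open-system scenarios."""
    return cw.single_channel_chain(4, 0.1, 1e-3)


@pytest.fixture(scope="session")
def bridge_chain_nnn():
    return cw.multichannel_chain(4, 0.1, 1e-3)


def generic_peierls(chain, omega0=0.05, g=0.02, chi=0.01):
    """One mode modulating every bond's hopping and SOC, off-manifold."""
    return ModeSpec(omega0, (), tuple(PeierlsCoupling(b.key, g, chi) for b in chain.bonds))


def restored_peierls(chain, omega0=0.05):
    """Symmetry-restoring couplings g_i = t_i/10, chi_i = lam_i/10."""
    return ModeSpec(
        omega0, (), tuple(PeierlsCoupling(b.key, b.t / 10.0, b.lam / 10.0) for b in chain.bonds)
    )


def random_su2(rng):
    from ciss_wilson import su2_from_axis_angle

    return su2_from_axis_angle(rng.uniform(0, np.pi), rng.normal(size=3)).matrix
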