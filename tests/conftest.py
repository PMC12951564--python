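import numpy as np
import pytest

from glycotraj import builder
from glycotraj.model import Trajectory


@pytest.fixture(scope="session")
def chain12():
    """12-residue alpha-1,4 glucan at the restrained-helix targets."""
    spec = builder.ChainSpec(n_residues=12, phi_deg=103.0, psi_deg=115.0)
    return builder.build_chain(spec)


@pytest.fixture(scope="session")
def chain6():
    spec = builder.ChainSpec(n_residues=6, phi_deg=103.0, psi_deg=115.0)
    return builder.build_chain(spec)


@pytest.fixture(scope="session")
def two_state_ensemble():
    """0.7/0.3 mixture of two well-separated conformations, small noise."""
    spec = builder.EnsembleSpec(
        n_frames=200,
        noise_sigma_A=0.25,
        state_mixture=[
            (builder.ChainSpec(n_residues=6, phi_deg=103.0, psi_deg=115.0), 0.7),
            (builder.ChainSpec(n_residues=6, phi_deg=85.0, psi_deg=-145.0), 0.3),
        ],
        seed=11,
    )
    return builder.make_ensemble(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def single_frame_traj(top, frame) -> Trajectory:
    return Trajectory(topology=top, frames=[frame])
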