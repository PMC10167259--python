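import numpy as np
import pytest

from destraj.trajio import (Frame, SimulationBox, SiteGroup, Topology,
                            Trajectory)


@pytest.fixture
def box20():
    return SimulationBox([20.0, 20.0, 20.0])


def make_point_topology(n, label="X", mtype="OTHER"):
    """n single-atom molecules."""
    return Topology(
        site_labels=np.array([label] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        molecule_ids=np.arange(n),
        molecule_types=np.array([mtype] * n, dtype=object),
        charges=np.zeros(n),
        lj_depth=np.zeros(n),
        lj_rmin=np.zeros(n),
    )


def make_topology(site_labels, molecule_ids, molecule_types=None,
                  charges=None, lj_depth=None, lj_rmin=None, elements=None):
    n = len(site_labels)
    return Topology(
        site_labels=np.array(site_labels, dtype=object),
        elements=np.array(elements if elements is not None
                          else ["C"] * n, dtype=object),
        molecule_ids=np.asarray(molecule_ids),
        molecule_types=np.array(molecule_types if molecule_types is not None
                                else ["OTHER"] * n, dtype=object),
        charges=np.asarray(charges if charges is not None else np.zeros(n),
                           dtype=float),
        lj_depth=np.asarray(lj_depth if lj_depth is not None
                            else np.zeros(n), dtype=float),
        lj_rmin=np.asarray(lj_rmin if lj_rmin is not None
                           else np.ones(n), dtype=float),
    )


def single_frame_traj(positions, topology, box, velocities=None):
    return Trajectory([Frame(0.0, positions, box, velocities)], topology)


@pytest.fixture(scope="session")
def toy_mixture():
    """A mid-size seeded toy DES mixture shared across structural tests."""
    from destraj.synth import gen_toy_des_mixture
    return gen_toy_des_mixture(n_salt=60, n_fa=60, fa_type="CAP",
                               box=SimulationBox([50.0] * 3),
                               planted_fraction=0.5, n_water=30, seed=42)
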