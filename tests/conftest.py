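import numpy as np
import pytest

import fibrion as fb


@pytest.fixture(scope="session")
def binding_fixture():
    """A medium binding trajectory with known Markov ground truth."""
    kin = fb.BindingKinetics(p_on=0.3, p_off=0.1, n_ions=20, seed=11)
    traj, truth = fb.generate_binding_trajectory(kin, n_frames=2000)
    return kin, traj, truth


@pytest.fixture(scope="session")
def shell_fixture():
    """Four ions with exactly four shell waters each, no background."""
    spec = fb.HydrationSpec(shell_occupancy=4, shell_radius=2.4, shell_jitter=0.1,
                            bulk_density=0.0, exclusion_radius=2.0,
                            n_frames=40, seed=7)
    traj, truth = fb.generate_hydration_trajectory(spec, box=(30.0, 30.0, 30.0), n_ions=4)
    return spec, traj, truth


@pytest.fixture(scope="session")
def ideal_gas_fixture():
    """Uniform water background around grid centers: g(r) should be 1."""
    spec = fb.HydrationSpec(shell_occupancy=0, shell_radius=2.4, shell_jitter=0.1,
                            bulk_density=0.0334, exclusion_radius=0.0,
                            n_frames=75, seed=13)
    traj, _ = fb.generate_hydration_trajectory(spec, box=(30.0, 30.0, 30.0), n_ions=64)
    return traj


def make_tiny_random_trajectory(n_prot=10, n_ions=2, n_frames=5, seed=0, box=(12.0, 14.0, 16.0)):
    """Tiny random fixture with protein heavy atoms and monatomic ions."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n = n_prot + n_ions
    names = ["CA"] * n_prot + ["NA"] * n_ions
    elements = ["C"] * n_prot + ["NA"] * n_ions
    resids = list(range(1, n_prot + 1)) + list(range(n_prot + 1, n_prot + n_ions + 1))
    resnames = ["GLY"] * n_prot + ["NA"] * n_ions
    chains = ["A"] * n_prot + ["B"] * n_ions
    groups = ["protein"] * n_prot + ["ion:NA"] * n_ions
    topo = fb.SystemTopology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_indices=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        groups=np.array(groups, dtype=object),
    )
    frames = [
        fb.Frame(time=float(t), positions=rng.random((n, 3)) * box, box=box)
        for t in range(n_frames)
    ]
    return fb.Trajectory(topology=topo, frames=frames)
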