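import numpy as np
import pytest

from groovescope.structio import Atom, Topology


def make_topology(specs, groups=None):
    """Build a Topology from (name, element, res_name, res_id, chain, mass) tuples."""
    atoms = [
        Atom(serial=i + 1, name=s[0], element=s[1], res_name=s[2], res_id=s[3],
             chain_id=s[4], mass=s[5] if len(s) > 5 else 12.0)
        for i, s in enumerate(specs)
    ]
    topo = Topology(atoms, groups or {})
    if groups is None:
        topo.default_groups()
    return topo


def water_topology(n_waters, three_site=False):
    """Oxygen-only (or 3-site) waters on chain W."""
    specs = []
    for w in range(1, n_waters + 1):
        specs.append(("O", "O", "HOH", w, "W", 15.999))
        if three_site:
            specs.append(("H1", "H", "HOH", w, "W", 1.008))
            specs.append(("H2", "H", "HOH", w, "W", 1.008))
    return make_topology(specs)


def peptide_topology(n_res, chain="L", res_name="ALA", with_cb=False):
    """Backbone-only peptide; optionally one CB side-chain atom per residue."""
    specs = []
    for r in range(1, n_res + 1):
        for name, el, m in (("N", "N", 14.007), ("CA", "C", 12.011),
                            ("C", "C", 12.011), ("O", "O", 15.999)):
            specs.append((name, el, res_name, r, chain, m))
        if with_cb:
            specs.append(("CB", "C", res_name, r, chain, 12.011))
    return make_topology(specs)


@pytest.fixture(scope="session")
def default_synthetic():
    """A moderately sized synthetic complex shared across tests."""
    from groovescope.synthetic import TrajectorySpec, make_complex_trajectory

    n = 60
    spec = TrajectorySpec(
        n_frames=n,
        rotation_schedule=np.linspace(0.0, 30.0, n),
        hydration_schedule=np.r_[np.full(n // 2, 6), np.full(n - n // 2, 2)],
        contact_schedule=np.r_[np.zeros(n // 2, bool), np.ones(n - n // 2, bool)],
        noise_sigma=0.02,
        seed=1234,
    )
    topology, trajectory, table = make_complex_trajectory(spec)
    return spec, topology, trajectory, table
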