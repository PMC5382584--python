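import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from groovescope.geometry import (
    ScalarSeries,
    backbone_rmsd_series,
    center_of_mass,
    convergence_time,
    helical_rotation_series,
    kabsch_superpose,
    principal_axis,
)
from groovescope.structio import AtomSelection, Trajectory, select

from conftest import make_topology, peptide_topology


def _sel(n):
    return AtomSelection(np.arange(n))


# ---------------------------------------------------------------------------
# centre of mass / principal axis
# ---------------------------------------------------------------------------

def test_center_of_mass_symmetry_and_identity():
    topo = make_topology([("A", "C", "X", 1, "A", 1.0), ("B", "C", "X", 2, "A", 1.0)])
    frame = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    assert np.allclose(center_of_mass(topo, _sel(2), frame), 0.0)
    single = AtomSelection(np.array([0]))
    assert np.allclose(center_of_mass(topo, single, frame), frame[0])


def test_center_of_mass_matches_direct_sum():
    rng = np.random.default_rng(5)
    masses = rng.uniform(1, 20, 50)
    topo = make_topology([("CA", "C", "X", i + 1, "A", m) for i, m in enumerate(masses)])
    frame = rng.normal(0, 10, (50, 3))
    expected = (frame * masses[:, None]).sum(axis=0) / masses.sum()
    assert np.allclose(center_of_mass(topo, _sel(50), frame), expected, atol=1e-10)


def test_center_of_mass_rejects_zero_mass():
    topo = make_topology([("CA", "C", "X", i + 1, "A", 0.0) for i in range(3)])
    with pytest.raises(ValueError):
        center_of_mass(topo, _sel(3), np.zeros((3, 3)))


def test_principal_axis_collinear_orientation():
    topo = make_topology([("CA", "C", "X", i + 1, "A", 12.0) for i in range(10)])
    frame = np.column_stack([np.full(10, 0.1) * np.arange(10) % 2 * 0.01,
                             np.zeros(10), np.arange(10, dtype=float)])
    axis = principal_axis(topo, _sel(10), frame)
    assert np.allclose(axis, [0, 0, 1], atol=1e-2)
    # reversed residue order flips the N->C orientation convention
    topo_rev = make_topology([("CA", "C", "X", 10 - i, "A", 12.0) for i in range(10)])
    axis_rev = principal_axis(topo_rev, _sel(10), frame[::-1])
    assert np.allclose(axis_rev, [0, 0, -1], atol=1e-2)


def test_principal_axis_of_ideal_helix_within_2_degrees():
    true_axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
    frame_z = np.column_stack([
        2.3 * np.cos(np.radians(100.0) * np.arange(20)),
        2.3 * np.sin(np.radians(100.0) * np.arange(20)),
        1.5 * np.arange(20),
    ])
    rot = Rotation.align_vectors([true_axis], [[0, 0, 1]])[0]
    frame = rot.apply(frame_z)
    topo = make_topology([("CA", "C", "X", i + 1, "A", 12.0) for i in range(20)])
    axis = principal_axis(topo, _sel(20), frame)
    angle = np.degrees(np.arccos(np.clip(abs(np.dot(axis, true_axis)), -1, 1)))
    assert angle < 2.0


def test_principal_axis_degenerate_raises():
    # a flat ring has two equal top eigenvalues: no unique axis
    ang = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
    topo = make_topology([("CA", "C", "X", i + 1, "A", 12.0) for i in range(100)])
    with pytest.raises(ValueError, match="degenerate"):
        principal_axis(topo, _sel(100), pts)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_kabsch_identity_translation_rotation():
    rng = np.random.default_rng(1)
    coords = rng.normal(0, 5, (20, 3))
    t, rmsd = kabsch_superpose(coords, coords)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-8)

    t, rmsd = kabsch_superpose(coords + [5, 5, 5], coords)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(t.translation, [-5, -5, -5], atol=1e-8)

    true_rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
    t, rmsd = kabsch_superpose(coords @ true_rot.T, coords)
    assert rmsd < 1e-8
    assert np.allclose(t.rotation, true_rot.T, atol=1e-6)


def test_kabsch_never_worse_than_unaligned():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.normal(0, 3, (8, 3))
        b = rng.normal(0, 3, (8, 3))
        w = rng.uniform(0.5, 2, 8)
        _, rmsd = kabsch_superpose(a, b, w)
        raw = np.sqrt((w * ((a - b) ** 2).sum(axis=1)).sum() / w.sum())
        assert rmsd <= raw + 1e-12


def test_kabsch_matches_numerical_search_on_5_atoms():
    """Optimal rotation cross-checked with a grid + simplex search oracle."""
    rng = np.random.default_rng(3)
    mobile = rng.normal(0, 3, (5, 3))
    reference = rng.normal(0, 3, (5, 3))
    _, rmsd = kabsch_superpose(mobile, reference)

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def cost(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(mob_c)
        return np.sqrt(((moved - ref_c) ** 2).sum(axis=1).mean())

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 5)
    for x in grid:
        for y in grid:
            for z in grid:
                res = minimize(cost, [x, y, z], method="Nelder-Mead",
                               options={"xatol": 1e-6, "fatol": 1e-10})
                best = min(best, res.fun)
    assert rmsd == pytest.approx(best, abs=1e-3)


def test_kabsch_rejects_tiny_systems():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

def _static_trajectory(topo, frame, n=5, transform=None):
    frames = []
    for f in range(n):
        x = frame.copy()
        if transform is not None:
            x = transform(x, f)
        frames.append(x)
    return Trajectory(coords=np.array(frames), times=np.arange(float(n)))


def test_rmsd_zero_for_identical_and_rigidly_moved_frames():
    topo = peptide_topology(5)
    rng = np.random.default_rng(4)
    frame = rng.normal(0, 5, (topo.n_atoms, 3))
    sel = _sel(topo.n_atoms)

    traj = _static_trajectory(topo, frame)
    out = backbone_rmsd_series(topo, traj, sel, sel, frame)
    assert np.allclose(out.values, 0, atol=1e-10)

    def rigid(x, f):
        rot = Rotation.from_euler("xyz", [10 * f, 5 * f, -3 * f], degrees=True)
        return rot.apply(x) + np.array([f, -f, 2.0 * f])

    traj = _static_trajectory(topo, frame, transform=rigid)
    out = backbone_rmsd_series(topo, traj, sel, sel, frame)
    assert np.allclose(out.values, 0, atol=1e-8)


def test_rmsd_of_gaussian_jitter_matches_analytic_expectation():
    """Per-atom jitter sigma gives mean RMSD ~= sqrt(3)*sigma for large n."""
    sigma, n_atoms = 0.5, 400
    topo = make_topology([("CA", "C", "X", i + 1, "A", 12.0) for i in range(n_atoms)])
    rng = np.random.default_rng(6)
    base = rng.normal(0, 10, (n_atoms, 3))
    frames = base + rng.normal(0, sigma, (30, n_atoms, 3))
    traj = Trajectory(coords=frames, times=np.arange(30.0))
    sel = _sel(n_atoms)
    out = backbone_rmsd_series(topo, traj, sel, sel, base)
    assert out.values.mean() == pytest.approx(np.sqrt(3) * sigma, rel=0.2)


# ---------------------------------------------------------------------------
# helical rotation
# ---------------------------------------------------------------------------

def _rotation_system(angles, noise=0.0, seed=0):
    from groovescope.synthetic import TrajectorySpec, make_complex_trajectory

    spec = TrajectorySpec(
        n_frames=len(angles), rotation_schedule=np.asarray(angles, float),
        noise_sigma=noise, seed=seed,
    )
    topo, traj, _ = make_complex_trajectory(spec)
    return (
        topo, traj,
        select(topo, "chain L and backbone"),
        select(topo, "chain A or chain B"),
    )


def test_rotation_zero_at_frame_zero_and_constructed_angles():
    topo, traj, lig, car = _rotation_system([0.0, 10.0, 38.44, 90.0, 180.0])
    out = helical_rotation_series(topo, traj, lig, car)
    assert out.values[0] == 0.0
    assert out.values[2] == pytest.approx(38.44, abs=0.01)
    assert out.values[4] == pytest.approx(180.0, abs=0.01)
    assert np.all((out.values >= 0) & (out.values <= 180))


def test_rotation_signed_variant_resolves_handedness():
    topo, traj, lig, car = _rotation_system([0.0, 25.0, -25.0])
    unsigned = helical_rotation_series(topo, traj, lig, car)
    signed = helical_rotation_series(topo, traj, lig, car, signed=True)
    assert unsigned.values[1] == pytest.approx(unsigned.values[2], abs=1e-6)
    assert signed.values[1] == pytest.approx(-signed.values[2], abs=1e-6)
    assert abs(signed.values[1]) == pytest.approx(25.0, abs=0.01)


def test_rotation_invariant_under_global_rigid_motion():
    topo, traj, lig, car = _rotation_system([0.0, 15.0, 38.44])
    base = helical_rotation_series(topo, traj, lig, car)
    rng = np.random.default_rng(7)
    moved = traj.coords.copy()
    for f in range(1, traj.n_frames):
        rot = Rotation.random(rng=rng)
        moved[f] = rot.apply(moved[f]) + rng.normal(0, 20, 3)
    traj2 = Trajectory(coords=moved, times=traj.times.copy(), box=traj.box)
    out = helical_rotation_series(topo, traj2, lig, car)
    assert np.allclose(out.values, base.values, atol=1e-6)


def test_rotation_invariant_under_carrier_relabeling():
    topo, traj, lig, car = _rotation_system([0.0, 20.0, 40.0])
    base = helical_rotation_series(topo, traj, lig, car)
    # uniform relabeling: same atom set presented in a different order
    shuffled = AtomSelection(car.indices[::-1].copy())
    out = helical_rotation_series(topo, traj, lig, shuffled)
    assert np.allclose(out.values, base.values, atol=1e-12)


def test_rotation_on_axis_carrier_is_rejected():
    topo = peptide_topology(4, chain="L")
    n = topo.n_atoms
    specs = [("CA", "C", "GLY", i + 1, "A", 12.0) for i in range(4)]
    from groovescope.structio import Atom, Topology

    atoms = topo.atoms + [
        Atom(serial=n + i + 1, name="CA", element="C", res_name="GLY",
             res_id=i + 1, chain_id="A", mass=12.0)
        for i in range(4)
    ]
    topo2 = Topology(atoms)
    topo2.default_groups()
    rng = np.random.default_rng(8)
    lig_coords = np.column_stack([
        2.3 * np.cos(np.radians(100.0) * np.arange(16)),
        2.3 * np.sin(np.radians(100.0) * np.arange(16)),
        1.5 * np.arange(16.0),
    ])
    car_coords = np.array([[0.01, -0.01, z] for z in (2.0, 8.0, 14.0, 20.0)])
    frame = np.vstack([lig_coords, car_coords])
    traj = Trajectory(coords=np.array([frame, frame]), times=np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="axis"):
        helical_rotation_series(
            topo2, traj, select(topo2, "chain L"), select(topo2, "chain A")
        )


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def test_convergence_constant_series_is_immediate():
    s = ScalarSeries(times=np.arange(0, 100.0), values=np.full(100, 2.0))
    t_star, plateau = convergence_time(s, window=5.0, tolerance=0.1)
    assert t_star == 0.0
    assert plateau == pytest.approx(2.0)


def test_convergence_ramp_never_settles():
    s = ScalarSeries(times=np.arange(0, 100.0), values=np.arange(100.0))
    assert convergence_time(s, window=5.0, tolerance=0.01) is None


def test_convergence_of_rmsd_like_rise_then_plateau():
    """Rise to 2.43 A by 20 ns then flat noise: settles in the 15-25 ns band."""
    rng = np.random.default_rng(9)
    times = np.arange(0, 160.0, 0.1)
    values = 2.43 * np.minimum(times / 20.0, 1.0) + rng.normal(0, 0.05, len(times))
    s = ScalarSeries(times=times, values=values)
    result = convergence_time(s, window=5.0, tolerance=0.1)
    assert result is not None
    t_star, plateau = result
    assert 15.0 <= t_star <= 25.0
    assert plateau == pytest.approx(2.43, abs=0.1)


def test_convergence_validates_input():
    with pytest.raises(ValueError):
        convergence_time(
            ScalarSeries(times=np.array([]), values=np.array([])), 5.0, 0.1
        )
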