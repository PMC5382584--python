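"""Synthetic carrier-ligand-water trajectories and assay traces.

Every analysis stage in this package is validated against data with known
ground truth.  The trajectory generator builds a minimal geometric model of
a chaperone dimer bound to a single transmembrane helix in a water box:

* ligand: an ideal 20-residue alpha-helix backbone (chain L, axis along z
  at frame 0), held fixed so the ligand frame is the ground-truth frame;
* carrier: two rigid pseudo-atom chains (A, B) forming an asymmetric
  groove around the ligand, rigid-rotated about the ligand principal axis
  by a prescribed per-frame rotation schedule;
* solvent: oxygen-only pseudo-waters, an exact per-frame number placed in
  the terminal hydration shell (3.0-4.7 A from terminal backbone atoms)
  and the remainder in bulk (> 7 A from every terminal heavy atom);
* contacts: a probe side-chain pseudo-atom on the ligand's last residue,
  placed within 4.0 A of a 4-atom pocket on chain A when the contact
  schedule is on, else > 8 A away.

Per-atom Gaussian jitter emulates thermal noise.  Everything is
deterministic under a fixed seed.  No force-field dynamics is implied:
the generator reproduces the statistical structure of the observables
(rotation drift and plateau, hydration-shell collapse, cluster dwell
schedules), not physical motion.

The assay generator produces linear NADH-decay A340 traces from a
prescribed specific activity with Gaussian absorbance noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from scipy.spatial.transform import Rotation

from .structio import (
    Atom,
    AtomSelection,
    Topology,
    Trajectory,
    apply_param_table,
    BACKBONE_NAMES,
)
from .geometry import center_of_mass, principal_axis
from .kinetics import AssayTrace, EPSILON_NADH_340, DEFAULT_PATH_LENGTH_CM

__all__ = [
    "TrajectorySpec",
    "AssaySpec",
    "GenerationError",
    "make_complex_trajectory",
    "make_assay_trace",
    "make_cluster_schedule",
    "LIGAND_N_RES",
    "PROBE_RESIDUE",
    "POCKET_SELECTION_EXPR",
]

LIGAND_N_RES = 20
#: (chain, res_id) of the probe residue carrying the side-chain pseudo-atom
PROBE_RESIDUE = ("L", LIGAND_N_RES)
#: selection expression for the carrier pocket atoms
POCKET_SELECTION_EXPR = "chain A and resname LYS MET ASP ILE"

N_BULK_WATERS = 50

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # deg per residue


class GenerationError(RuntimeError):
    """Raised when a spec cannot be realized geometrically."""


@dataclass
class TrajectorySpec:
    """Ground-truth schedules and noise level for a synthetic trajectory."""

    n_frames: int
    dt: float = 0.1  # ns
    rotation_schedule: np.ndarray = None  # deg per frame
    hydration_schedule: np.ndarray = None  # waters per frame
    contact_schedule: np.ndarray = None  # bool per frame
    noise_sigma: float = 0.0  # A
    box: tuple[float, float, float] = (80.0, 80.0, 80.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rotation_schedule is None:
            self.rotation_schedule = np.zeros(self.n_frames)
        if self.hydration_schedule is None:
            self.hydration_schedule = np.zeros(self.n_frames, dtype=int)
        if self.contact_schedule is None:
            self.contact_schedule = np.zeros(self.n_frames, dtype=bool)
        self.rotation_schedule = np.asarray(self.rotation_schedule, dtype=float)
        self.hydration_schedule = np.asarray(self.hydration_schedule, dtype=int)
        self.contact_schedule = np.asarray(self.contact_schedule, dtype=bool)
        for name in ("rotation_schedule", "hydration_schedule", "contact_schedule"):
            if len(getattr(self, name)) != self.n_frames:
                raise ValueError(f"{name} length must equal n_frames")
        if np.any(self.hydration_schedule < 0):
            raise ValueError("hydration counts must be >= 0")

    def ground_truth(self) -> dict:
        return {
            "seed": int(self.seed),
            "dt_ns": float(self.dt),
            "rotation_schedule_deg": self.rotation_schedule.tolist(),
            "hydration_schedule": self.hydration_schedule.tolist(),
            "contact_schedule": self.contact_schedule.astype(int).tolist(),
            "noise_sigma_A": float(self.noise_sigma),
        }


@dataclass
class AssaySpec:
    """Prescribed kinetics for a synthetic NADH-decay trace.

    The initial NADH concentration is 0.3 mM; the prescribed turnover must
    not deplete it before the end of the trace.
    """

    specific_activity: float  # nmol/min/mg
    enzyme_mass: float = 0.01  # mg
    volume: float = 200e-6  # L
    extinction_coeff: float = EPSILON_NADH_340
    path_length: float = DEFAULT_PATH_LENGTH_CM
    duration: float = 10.0  # min
    sample_interval: float = 10.0  # s
    noise_sigma: float = 0.0  # AU
    seed: int = 0
    enzyme: str = "enzyme"
    condition: str = "basal"

    NADH_M: float = 3.0e-4

    def __post_init__(self):
        for name in ("enzyme_mass", "volume", "extinction_coeff", "path_length",
                     "duration", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.specific_activity < 0 or self.noise_sigma < 0:
            raise ValueError("specific_activity and noise_sigma must be >= 0")

    @property
    def rate_m_per_s(self) -> float:
        """NADH consumption rate in M/s implied by the specific activity."""
        nmol_per_min = self.specific_activity * self.enzyme_mass
        return nmol_per_min * 1e-9 / 60.0 / self.volume


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def _helix_point(res: int, radius: float, phase_deg: float, z_offset: float):
    ang = np.radians(res * HELIX_TWIST + phase_deg)
    return np.array(
        [radius * np.cos(ang), radius * np.sin(ang), res * HELIX_RISE + z_offset]
    )


def _build_ligand() -> tuple[list[Atom], np.ndarray]:
    """Ideal helix backbone (N, CA, C, O) + probe CB on the last residue."""
    atoms, coords = [], []
    serial = 1
    for res in range(1, LIGAND_N_RES + 1):
        for name, element, radius, phase, dz in (
            ("N", "N", 1.6, -26.0, -0.9),
            ("CA", "C", 2.3, 0.0, 0.0),
            ("C", "C", 2.0, 21.0, 0.55),
            ("O", "O", 2.1, 23.0, 1.75),
        ):
            atoms.append(
                Atom(serial=serial, name=name, element=element, res_name="LEU",
                     res_id=res, chain_id="L")
            )
            coords.append(_helix_point(res - 1, radius, phase, dz))
            serial += 1
    # side-chain pseudo-atom of the probe residue; position set per frame
    atoms.append(
        Atom(serial=serial, name="CB", element="C", res_name="LEU",
             res_id=LIGAND_N_RES, chain_id="L")
    )
    coords.append(_helix_point(LIGAND_N_RES - 1, 3.6, 0.0, 0.3))
    return atoms, np.array(coords)


def _build_carrier() -> tuple[list[Atom], np.ndarray, np.ndarray]:
    """Two rigid arcs around the ligand; returns atoms, coords, pocket index.

    Chain A spans a wider arc than chain B so the carrier centre of mass
    sits a few Angstrom off the helix axis — a rotation about the axis then
    moves the COM by the same angle, which is what the rotation metric
    measures.
    """
    atoms, coords = [], []
    serial = 1000
    res_id = 1
    z_levels = (2.0, 8.5, 15.0, 21.5, 28.0)

    def add_arc(chain, radius, start_deg, end_deg, n_per_level, res_name="ALA"):
        nonlocal serial, res_id
        for z in z_levels:
            for ang in np.linspace(start_deg, end_deg, n_per_level):
                atoms.append(
                    Atom(serial=serial, name="CA", element="C", res_name=res_name,
                         res_id=res_id, chain_id=chain)
                )
                a = np.radians(ang)
                coords.append([radius * np.cos(a), radius * np.sin(a), z])
                serial += 1
                res_id += 1

    add_arc("A", 11.0, -60.0, 60.0, 36)
    add_arc("B", 11.0, 160.0, 200.0, 6)

    # induced pocket: four atoms on chain A near the ligand C-terminal end
    pocket_start = len(atoms)
    for res_name, ang, z in (
        ("LYS", 40.0, 26.0), ("MET", 50.0, 27.0),
        ("ASP", 60.0, 27.5), ("ILE", 70.0, 26.5),
    ):
        atoms.append(
            Atom(serial=serial, name="CA", element="C", res_name=res_name,
                 res_id=res_id, chain_id="A")
        )
        a = np.radians(ang)
        coords.append([6.5 * np.cos(a), 6.5 * np.sin(a), z])
        serial += 1
        res_id += 1
    pocket_idx = np.arange(pocket_start, len(atoms))
    return atoms, np.array(coords), pocket_idx


DEFAULT_PARAM_TABLE = {
    ("LEU", "N"): dict(charge=-0.35, lj_sigma=3.25, lj_epsilon=0.17, born_radius=1.55, mass=14.007),
    ("LEU", "CA"): dict(charge=0.05, lj_sigma=3.40, lj_epsilon=0.11, born_radius=1.70, mass=12.011),
    ("LEU", "C"): dict(charge=0.50, lj_sigma=3.40, lj_epsilon=0.09, born_radius=1.70, mass=12.011),
    ("LEU", "O"): dict(charge=-0.55, lj_sigma=2.96, lj_epsilon=0.21, born_radius=1.50, mass=15.999),
    ("LEU", "CB"): dict(charge=-0.05, lj_sigma=3.50, lj_epsilon=0.12, born_radius=1.70, mass=12.011),
    ("ALA", "CA"): dict(charge=0.10, lj_sigma=3.40, lj_epsilon=0.11, born_radius=1.70, mass=12.011),
    ("LYS", "CA"): dict(charge=0.25, lj_sigma=3.40, lj_epsilon=0.11, born_radius=1.70, mass=12.011),
    ("MET", "CA"): dict(charge=0.02, lj_sigma=3.40, lj_epsilon=0.11, born_radius=1.70, mass=12.011),
    ("ASP", "CA"): dict(charge=-0.30, lj_sigma=3.40, lj_epsilon=0.11, born_radius=1.70, mass=12.011),
    ("ILE", "CA"): dict(charge=0.01, lj_sigma=3.40, lj_epsilon=0.11, born_radius=1.70, mass=12.011),
    ("WAT", "O"): dict(charge=-0.83, lj_sigma=3.15, lj_epsilon=0.152, born_radius=1.50, mass=15.999),
}


def make_complex_trajectory(
    spec: TrajectorySpec,
) -> tuple[Topology, Trajectory, dict]:
    """Generate a carrier-ligand-water trajectory realizing the spec exactly.

    Returns (topology, trajectory, parameter table); the table is already
    applied to the topology.  Ground-truth schedules are available from
    ``spec.ground_truth()``.
    """
    rng = np.random.default_rng(spec.seed)
    lig_atoms, lig_coords = _build_ligand()
    car_atoms, car_coords, pocket_local = _build_carrier()
    n_lig, n_car = len(lig_atoms), len(car_atoms)
    pocket_idx = pocket_local + n_lig
    probe_idx = n_lig - 1  # the CB pseudo-atom

    # heavy atoms of the first/last two ligand residues (backbone only used
    # as water anchors; the full set is used for bulk exclusion)
    terminal_res = {1, 2, LIGAND_N_RES - 1, LIGAND_N_RES}
    anchor_idx = np.array(
        [i for i, a in enumerate(lig_atoms)
         if a.res_id in terminal_res and a.name != "CB"],
        dtype=int,
    )
    terminal_idx = np.array(
        [i for i, a in enumerate(lig_atoms) if a.res_id in terminal_res], dtype=int
    )

    max_shell = int(spec.hydration_schedule.max(initial=0))
    if max_shell > 3 * len(anchor_idx):
        raise GenerationError(
            f"hydration count {max_shell} exceeds placeable shell sites "
            f"({3 * len(anchor_idx)})"
        )
    n_waters = max_shell + N_BULK_WATERS

    wat_atoms = []
    serial = 9000
    for w in range(n_waters):
        wat_atoms.append(
            Atom(serial=serial + w, name="O", element="O", res_name="WAT",
                 res_id=w + 1, chain_id="W")
        )
    atoms = lig_atoms + car_atoms + wat_atoms
    topology = Topology(atoms)
    topology.default_groups()
    unmatched = apply_param_table(topology, DEFAULT_PARAM_TABLE)
    if unmatched:
        raise GenerationError(f"parameter table does not cover atoms {unmatched}")

    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    n_atoms = len(atoms)
    coords = np.empty((spec.n_frames, n_atoms, 3))

    # the rotation axis is exactly what the analysis measures about: the
    # ligand backbone's principal axis, through its mass-weighted COM
    lig_bb = AtomSelection(
        np.array(
            [i for i, a in enumerate(lig_atoms)
             if a.name in BACKBONE_NAMES],
            dtype=int,
        )
    )
    frame0 = np.vstack([lig_coords, car_coords, np.zeros((n_waters, 3))])
    axis = principal_axis(topology, lig_bb, frame0)
    axis_origin = center_of_mass(topology, lig_bb, frame0)

    for f in range(spec.n_frames):
        frame = np.empty((n_atoms, 3))
        # ligand fixed; carrier rigid-rotated about the ligand helix axis
        rot = Rotation.from_rotvec(
            np.radians(spec.rotation_schedule[f]) * axis
        ).as_matrix()
        frame[:n_lig] = lig_coords
        frame[n_lig:n_lig + n_car] = (car_coords - axis_origin) @ rot.T + axis_origin
        # thermal jitter on the carrier; the ligand is held literally fixed,
        # being the ground-truth reference frame everything is measured in
        if spec.noise_sigma > 0:
            frame[n_lig:n_lig + n_car] += rng.normal(
                0.0, spec.noise_sigma, (n_car, 3)
            )
        # probe side chain: docked axially above the (rotated, jittered)
        # pocket ring — 3.5-3.9 A from every pocket atom, clear of both the
        # carrier wall and the ligand backbone — or withdrawn 10 A along
        # the axis when the contact is off
        pocket_now = frame[pocket_idx]
        pocket_center = pocket_now.mean(axis=0)
        if spec.contact_schedule[f]:
            frame[probe_idx] = pocket_center + 4.4 * axis
        else:
            frame[probe_idx] = pocket_center + 10.0 * axis

        # shell waters at exact distances from jittered anchor atoms
        k = int(spec.hydration_schedule[f])
        anchors = frame[anchor_idx]
        w = 0
        for w in range(k):
            anchor = anchors[w % len(anchors)]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r = rng.uniform(3.0, 4.7)
            frame[n_lig + n_car + w] = anchor + r * direction
        # remaining waters in bulk: > 7 A (min image) from terminal atoms
        terminal_now = frame[terminal_idx]
        for w in range(k, n_waters):
            for _ in range(200):
                pos = rng.uniform(-center, center)
                delta = pos - terminal_now
                delta -= box * np.round(delta / box)
                if np.sqrt((delta**2).sum(axis=1)).min() > 7.5:
                    frame[n_lig + n_car + w] = pos
                    break
            else:  # pragma: no cover
                raise GenerationError("could not place bulk water")
        coords[f] = frame + center  # shift system to box centre

    times = np.arange(spec.n_frames) * spec.dt
    frame_box = np.broadcast_to(box, (spec.n_frames, 3)).copy()
    trajectory = Trajectory(coords=coords, times=times, box=frame_box)
    return topology, trajectory, dict(DEFAULT_PARAM_TABLE)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def make_cluster_schedule(
    segments: list[tuple[tuple[float, int], float, float]],
    dt: float,
    rotation_jitter: float = 0.4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant schedules from dwell segments.

    ``segments`` is an ordered list of ((rotation_deg, hydration_count),
    start_ns, end_ns); segments must be contiguous and non-overlapping,
    starting at 0.  Each frame at time f*dt takes its segment's state; the
    rotation gets uniform within-state jitter of +/- ``rotation_jitter``
    degrees (hydration, being an integer count, gets none).
    """
    if not segments:
        raise ValueError("empty segment list")
    t = 0.0
    for state, start, end in segments:
        if end <= start:
            raise ValueError(f"segment {state} has non-positive span")
        if abs(start - t) > 1e-9:
            raise ValueError(
                f"segments must be contiguous from 0; got start {start} after {t}"
            )
        t = end
    rng = np.random.default_rng(seed)
    n_frames = int(round(t / dt))
    rotation = np.empty(n_frames)
    hydration = np.empty(n_frames, dtype=int)
    for f in range(n_frames):
        tf = f * dt
        for (rot, hyd), start, end in segments:
            if start - 1e-9 <= tf < end - 1e-9 or (tf >= end - 1e-9 and end == t):
                rotation[f] = rot + rng.uniform(-rotation_jitter, rotation_jitter)
                hydration[f] = hyd
                break
    return rotation, hydration


def segment_frame_ranges(
    segments: list[tuple[tuple[float, int], float, float]], dt: float
) -> list[tuple[int, int]]:
    """First/last frame index of each segment (inclusive), for test oracles."""
    total = segments[-1][2]
    n_frames = int(round(total / dt))
    ranges = []
    for _, start, end in segments:
        first = int(np.ceil(start / dt - 1e-9))
        last = min(int(np.ceil(end / dt - 1e-9)) - 1, n_frames - 1)
        ranges.append((first, last))
    return ranges


# ---------------------------------------------------------------------------
# assay traces
# ---------------------------------------------------------------------------

def make_assay_trace(spec: AssaySpec) -> AssayTrace:
    """Linear NADH-decay A340 trace with Gaussian absorbance noise.

    A340(t) = A0 - eps * l * rate * t + N(0, noise_sigma), with
    A0 = eps * l * [NADH]_0 and rate the M/s consumption implied by the
    prescribed specific activity.
    """
    duration_s = spec.duration * 60.0
    consumed = spec.rate_m_per_s * duration_s
    if consumed > spec.NADH_M:
        raise ValueError(
            f"prescribed activity depletes NADH ({consumed * 1e3:.3f} mM "
            f"of {spec.NADH_M * 1e3:.1f} mM) before the trace ends"
        )
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, duration_s + 1e-9, spec.sample_interval)
    a0 = spec.extinction_coeff * spec.path_length * spec.NADH_M
    a340 = a0 - spec.extinction_coeff * spec.path_length * spec.rate_m_per_s * times
    if spec.noise_sigma > 0:
        a340 = a340 + rng.normal(0.0, spec.noise_sigma, len(times))
    return AssayTrace(
        times=times,
        a340=a340,
        enzyme=spec.enzyme,
        condition=spec.condition,
        enzyme_mass=spec.enzyme_mass,
        volume=spec.volume,
        path_length=spec.path_length,
        extinction_coeff=spec.extinction_coeff,
    )


def write_ground_truth(spec: TrajectorySpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.ground_truth(), fh)
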