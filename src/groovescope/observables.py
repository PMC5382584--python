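"""Solvation and contact observables.

Terminal hydration: number of water molecules (represented by their oxygen
atom) within a cutoff of any heavy atom of the first and last few residues
of the bound transmembrane helix — the ligand's hydration shell, which
closes down as the carrier's lid shields the helix from solvent.

Contacts: per-frame minimum heavy-atom distance between a probe residue's
side chain and a designated pocket atom set, thresholded into a 0/1 contact
series.

All distances use the minimum-image convention when the trajectory carries
an orthorhombic box; the boundary is inclusive (d <= cutoff counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structio import AtomSelection, Topology, Trajectory, BACKBONE_NAMES
from .geometry import ScalarSeries

__all__ = [
    "HydrationSpec",
    "ContactSpec",
    "minimum_image_distances",
    "terminal_hydration_series",
    "residue_contact_series",
]

logger = logging.getLogger("groovescope")


@dataclass
class HydrationSpec:
    """How many residues per terminus and the shell cutoff (default 5 A)."""

    terminal_residue_count: int = 2
    cutoff: float = 5.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.terminal_residue_count < 1:
            raise ValueError("terminal_residue_count must be >= 1")


@dataclass
class ContactSpec:
    """Probe residue (chain, res_id) vs pocket atoms, contact cutoff in A."""

    probe_residue: tuple[str, int]
    pocket_atoms: AtomSelection = field(default=None)
    cutoff: float = 4.5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.pocket_atoms is None or len(self.pocket_atoms) == 0:
            raise ValueError("pocket_atoms must be a non-empty selection")


def minimum_image_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Pairwise distance matrix (len(a) x len(b)), minimum image if boxed.

    ``box`` is either None (raw distances) or the three orthorhombic edge
    lengths in Angstrom.
    """
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=-1))


def _terminal_heavy_indices(
    topology: Topology, ligand_chain: str, n_terminal: int
) -> np.ndarray:
    res_ids = sorted(
        {a.res_id for a in topology.atoms if a.chain_id == ligand_chain}
    )
    if len(res_ids) < 2 * n_terminal:
        raise ValueError(
            f"ligand chain {ligand_chain!r} has {len(res_ids)} residues; "
            f"needs >= {2 * n_terminal}"
        )
    terminal = set(res_ids[:n_terminal]) | set(res_ids[-n_terminal:])
    return np.array(
        [
            i
            for i, a in enumerate(topology.atoms)
            if a.chain_id == ligand_chain and a.res_id in terminal and a.is_heavy
        ],
        dtype=int,
    )


def terminal_hydration_series(
    topology: Topology,
    trajectory: Trajectory,
    ligand_chain: str,
    spec: HydrationSpec | None = None,
) -> ScalarSeries:
    """Waters within ``spec.cutoff`` of the ligand's terminal residues, per frame.

    A water is counted if its oxygen is within the cutoff of ANY heavy atom
    of the first or last ``terminal_residue_count`` residues of the ligand
    chain; each water is counted at most once even if near both termini.
    """
    spec = spec or HydrationSpec()
    terminal_idx = _terminal_heavy_indices(
        topology, ligand_chain, spec.terminal_residue_count
    )
    water_idx = topology.water_oxygen_indices()
    if len(water_idx) == 0:
        logger.warning("no waters in topology; hydration series is all zero")
        return ScalarSeries(
            times=trajectory.times.copy(),
            values=np.zeros(trajectory.n_frames),
            label="terminal_hydration_count",
        )
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        d = minimum_image_distances(
            frame[water_idx], frame[terminal_idx], trajectory.frame_box(f)
        )
        values[f] = int(np.count_nonzero((d <= spec.cutoff).any(axis=1)))
    return ScalarSeries(
        times=trajectory.times.copy(), values=values, label="terminal_hydration_count"
    )


def residue_contact_series(
    topology: Topology, trajectory: Trajectory, spec: ContactSpec
) -> tuple[ScalarSeries, ScalarSeries]:
    """Per-frame probe-side-chain/pocket contact flag and minimum distance.

    Returns (contact 0/1 series, minimum heavy-atom distance series in A);
    contact(f) = 1 iff the minimum-image distance d(f) <= spec.cutoff.
    """
    chain, res_id = spec.probe_residue
    probe_idx = np.array(
        [
            i
            for i, a in enumerate(topology.atoms)
            if a.chain_id == chain
            and a.res_id == res_id
            and a.is_heavy
            and a.name not in BACKBONE_NAMES
        ],
        dtype=int,
    )
    if len(probe_idx) == 0:
        raise ValueError(
            f"probe residue {chain}:{res_id} has no side-chain heavy atoms"
        )
    pocket_idx = spec.pocket_atoms.indices
    dist = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        d = minimum_image_distances(
            frame[probe_idx], frame[pocket_idx], trajectory.frame_box(f)
        )
        dist[f] = d.min()
    flags = (dist <= spec.cutoff).astype(float)
    times = trajectory.times
    return (
        ScalarSeries(times=times.copy(), values=flags, label="contact"),
        ScalarSeries(times=times.copy(), values=dist, label="min_distance_A"),
    )
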