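"""Geometric trajectory observables.

Implements mass-weighted centres of mass, principal (helix) axes, optimal
rigid superposition, backbone RMSD time series, the helical-rotation metric
and plateau/convergence detection.

The helical-rotation metric quantifies how far the carrier protein has
revolved around the bound transmembrane helix: after aligning every frame to
the ligand backbone of frame 0, it is the angle between the axis-normal
component of the carrier-to-ligand centre-of-mass vector at time zero and at
time t, measured about the ligand helix axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomSelection, Topology, Trajectory

__all__ = [
    "ScalarSeries",
    "RigidTransform",
    "center_of_mass",
    "principal_axis",
    "kabsch_superpose",
    "backbone_rmsd_series",
    "helical_rotation_series",
    "convergence_time",
]


@dataclass
class ScalarSeries:
    """A time-indexed scalar observable (deg, Angstrom, count, 0/1, ...)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_tsv(self, path) -> None:
        header = f"time_ns\t{self.label or 'value'}"
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.6g",
        )

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "ScalarSeries":
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(times=data[:, 0], values=data[:, 1], label=label)


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def center_of_mass(
    topology: Topology, selection: AtomSelection, frame: np.ndarray
) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (Angstrom)."""
    idx = selection.indices
    if len(idx) == 0:
        raise ValueError("empty selection")
    masses = topology.masses()[idx]
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    return (frame[idx] * masses[:, None]).sum(axis=0) / total


def principal_axis(
    topology: Topology, selection: AtomSelection, frame: np.ndarray
) -> np.ndarray:
    """Unit vector along the dominant extent of the selection.

    The axis is the top eigenvector of the (unweighted) coordinate covariance
    tensor, oriented to point from the first selected residue toward the last
    (N- to C-terminus for a protein chain in file order).
    """
    idx = selection.indices
    if len(idx) < 3:
        raise ValueError("principal axis needs at least 3 atoms")
    coords = frame[idx]
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(idx)
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending; the last column is the dominant axis
    if evals[2] <= 0 or (evals[2] - evals[1]) / evals[2] < 1e-6:
        raise ValueError("degenerate principal axis (top eigenvalue not unique)")
    axis = evecs[:, 2]
    # orient from first to last selected residue
    res_keys = [
        (topology.atoms[i].chain_id, topology.atoms[i].res_id) for i in idx
    ]
    first_key, last_key = res_keys[0], res_keys[-1]
    first_pts = coords[[k == first_key for k in res_keys]]
    last_pts = coords[[k == last_key for k in res_keys]]
    direction = last_pts.mean(axis=0) - first_pts.mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[RigidTransform, float]:
    """Weighted least-squares rigid superposition of mobile onto reference.

    Returns the transform and the post-fit weighted RMSD (Angstrom).  The
    reflection branch of the underlying SVD is handled by scipy, so the
    returned rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    mob_c = (mobile * weights[:, None]).sum(axis=0) / wsum
    ref_c = (reference * weights[:, None]).sum(axis=0) / wsum
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c, weights=weights)
    rot_mat = rot.as_matrix()
    transform = RigidTransform(rotation=rot_mat, translation=ref_c - rot_mat @ mob_c)
    moved = transform.apply(mobile)
    rmsd = float(
        np.sqrt((weights * ((moved - reference) ** 2).sum(axis=1)).sum() / wsum)
    )
    return transform, rmsd


def backbone_rmsd_series(
    topology: Topology,
    trajectory: Trajectory,
    fit_selection: AtomSelection,
    measure_selection: AtomSelection,
    reference_frame: np.ndarray,
    label: str = "rmsd_A",
) -> ScalarSeries:
    """Per-frame mass-weighted RMSD after superposing on ``fit_selection``.

    Each frame is superposed onto the reference using the fit selection
    (mass-weighted), then the RMSD over ``measure_selection`` is reported.
    """
    if len(fit_selection) == 0 or len(measure_selection) == 0:
        raise ValueError("selections must be non-empty")
    masses = topology.masses()
    fit_idx = fit_selection.indices
    meas_idx = measure_selection.indices
    ref_fit = reference_frame[fit_idx]
    ref_meas = reference_frame[meas_idx]
    w_meas = masses[meas_idx]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        transform, _ = kabsch_superpose(frame[fit_idx], ref_fit, masses[fit_idx])
        moved = transform.apply(frame[meas_idx])
        values[f] = np.sqrt(
            (w_meas * ((moved - ref_meas) ** 2).sum(axis=1)).sum() / w_meas.sum()
        )
    return ScalarSeries(times=trajectory.times.copy(), values=values, label=label)


def helical_rotation_series(
    topology: Topology,
    trajectory: Trajectory,
    ligand_backbone: AtomSelection,
    carrier: AtomSelection,
    signed: bool = False,
) -> ScalarSeries:
    """Rotation of the carrier about the ligand helix axis, per frame (deg).

    Algorithm, per frame f:

    1. superpose the frame onto frame 0 using the ligand backbone;
    2. take the helix axis ``a`` = principal axis of the ligand backbone in
       frame 0 (frames share the ligand frame after alignment, so the axis
       is computed once);
    3. form v_f = COM(carrier) - COM(ligand backbone) in the aligned frame;
    4. project off the axis: p_f = v_f - (v_f . a) a;
    5. theta(f) = angle between p_0 and p_f, in [0, 180] degrees.

    theta(0) is exactly 0.  With ``signed=True`` the angle is measured about
    +a with range (-180, 180].
    """
    if len(ligand_backbone) < 3:
        raise ValueError("ligand backbone selection needs >= 3 atoms")
    if len(carrier) == 0:
        raise ValueError("carrier selection is empty")
    masses = topology.masses()
    lig_idx = ligand_backbone.indices
    frame0 = trajectory.coords[0]
    axis = principal_axis(topology, ligand_backbone, frame0)

    def offset_vector(frame: np.ndarray) -> np.ndarray:
        v = center_of_mass(topology, carrier, frame) - center_of_mass(
            topology, ligand_backbone, frame
        )
        return v - np.dot(v, axis) * axis

    p0 = offset_vector(frame0)
    if np.linalg.norm(p0) < 0.5:
        raise ValueError(
            "carrier COM lies on the ligand axis at frame 0; rotation undefined"
        )
    values = np.empty(trajectory.n_frames)
    values[0] = 0.0
    ref_lig = frame0[lig_idx]
    w_lig = masses[lig_idx]
    for f in range(1, trajectory.n_frames):
        frame = trajectory.coords[f]
        transform, _ = kabsch_superpose(frame[lig_idx], ref_lig, w_lig)
        aligned = transform.apply(frame)
        p = offset_vector(aligned)
        norm = np.linalg.norm(p)
        if norm < 0.5:
            raise ValueError(
                f"frame {f}: carrier COM within 0.5 A of the ligand axis; "
                "rotation angle undefined"
            )
        cross = np.cross(p0, p)
        theta = np.degrees(np.arctan2(np.linalg.norm(cross), np.dot(p0, p)))
        if signed and np.dot(cross, axis) < 0:
            theta = -theta
        values[f] = theta
    return ScalarSeries(
        times=trajectory.times.copy(), values=values, label="helical_rotation_deg"
    )


def convergence_time(
    series: ScalarSeries, window: float, tolerance: float
) -> tuple[float, float] | None:
    """Earliest time from which all running-window means stay on the plateau.

    The plateau value is the mean of the final 20% of the series.  The
    function returns the earliest time t* such that the mean over every full
    window [t, t + window] with t >= t* lies within +/- tolerance of the
    plateau, together with the plateau value; None if no such t* exists.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    times, values = series.times, series.values
    span = times[-1] - times[0]
    if window >= span:
        raise ValueError("window must be smaller than the series span")
    tail_start = times[0] + 0.8 * span
    plateau = float(values[times >= tail_start].mean())

    starts = np.nonzero(times + window <= times[-1] + 1e-12)[0]
    ok = np.empty(len(starts), dtype=bool)
    for k, i in enumerate(starts):
        in_win = (times >= times[i]) & (times <= times[i] + window + 1e-12)
        ok[k] = abs(values[in_win].mean() - plateau) <= tolerance
    # earliest index from which every subsequent window mean is on-plateau
    good_from = None
    for k in range(len(starts) - 1, -1, -1):
        if not ok[k]:
            break
        good_from = starts[k]
    if good_from is None:
        return None
    return float(times[good_from]), plateau
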