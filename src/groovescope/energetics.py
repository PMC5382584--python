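"""Pairwise carrier-ligand interaction enthalpies.

A generalized-Born screened electrostatics term plus a Lennard-Jones term,
summed over all inter-group atom pairs, gives a per-frame interaction
enthalpy surrogate; averaging over the member frames of each population
cluster yields a per-cluster enthalpy report.  This is a pairwise-GB
interaction surrogate with fixed per-atom Born radii — it deliberately
omits the nonpolar/SASA solvation term and per-snapshot effective-radius
recomputation of full MM-GBSA, while preserving the comparative
per-cluster analysis.

For charges q_i, q_j (e) at minimum-image distance r (A):

    E_elec = k_e q_i q_j [ 1/(eps_p r) - (1/eps_p - 1/eps_w) / f_GB ]
    f_GB   = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j)))

with k_e = 332.0636 kcal A / (mol e^2); f_GB -> r when either Born radius
is zero (fully screened limit), and with ``use_gb=False`` the vacuum
Coulomb form k_e q_i q_j / (eps_p r) is used.  The Lennard-Jones term uses
Lorentz-Berthelot combining.  Favorable interactions are negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structio import AtomSelection, Topology, Trajectory
from .population import Cluster

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyModel",
    "EnergyReport",
    "ClashError",
    "pair_interaction_energy",
    "cluster_mean_enthalpy",
]

logger = logging.getLogger("groovescope")

#: Electrostatic conversion constant, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0636


class ClashError(ValueError):
    """Raised when an inter-group pair is closer than the clash distance."""


@dataclass
class EnergyModel:
    """Dielectrics and switches for the pairwise interaction energy."""

    eps_protein: float = 1.0
    eps_water: float = 78.5
    use_gb: bool = True
    cutoff: float | None = None  # A; None = no cutoff

    def __post_init__(self):
        if self.eps_protein < 1 or self.eps_water < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive or None")


@dataclass
class EnergyReport:
    """Per-cluster mean/sd interaction enthalpies with components."""

    per_cluster: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            str(cid): {
                "mean_kcal_mol": entry["mean"],
                "abs_mean_kcal_mol": abs(entry["mean"]),
                "sd_kcal_mol": entry["sd"],
                "n_frames": entry["n_frames"],
                "elec_kcal_mol": entry["elec"],
                "vdw_kcal_mol": entry["vdw"],
            }
            for cid, entry in self.per_cluster.items()
        }


def _gather_params(topology: Topology, idx: np.ndarray, what: str) -> tuple:
    q = np.array([topology.atoms[i].charge for i in idx])
    sig = np.array([topology.atoms[i].lj_sigma for i in idx])
    eps = np.array([topology.atoms[i].lj_epsilon for i in idx])
    born = np.array([topology.atoms[i].born_radius for i in idx])
    for name, arr in (("charge", q), ("lj_sigma", sig), ("lj_epsilon", eps),
                      ("born_radius", born)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {what}: non-finite {name} parameters")
    return q, sig, eps, born


def pair_interaction_energy(
    topology: Topology,
    frame: np.ndarray,
    group_a: AtomSelection,
    group_b: AtomSelection,
    model: EnergyModel | None = None,
    box: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Inter-group interaction energy for one frame: (total, elec, vdw) kcal/mol."""
    model = model or EnergyModel()
    ia, ib = group_a.indices, group_b.indices
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    if ib[0] < ia[0]:  # canonical order makes E(A,B) == E(B,A) bitwise exact
        ia, ib = ib, ia
    qa, siga, epsa, borna = _gather_params(topology, ia, "A")
    qb, sigb, epsb, bornb = _gather_params(topology, ib, "B")

    delta = frame[ia][:, None, :] - frame[ib][None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        delta -= box * np.round(delta / box)
    r = np.sqrt((delta**2).sum(axis=-1))
    if np.any(r < 0.1):
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ClashError(
            f"atoms {topology.atoms[ia[i]].serial} and "
            f"{topology.atoms[ib[j]].serial} at {r[i, j]:.3f} A (< 0.1 A)"
        )

    qq = COULOMB_CONSTANT * np.outer(qa, qb)
    if model.use_gb:
        rr = np.outer(borna, bornb)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_gb = np.where(
                rr > 0, np.sqrt(r**2 + rr * np.exp(-(r**2) / (4 * rr))), r
            )
        elec_pair = qq * (
            1.0 / (model.eps_protein * r)
            - (1.0 / model.eps_protein - 1.0 / model.eps_water) / f_gb
        )
    else:
        elec_pair = qq / (model.eps_protein * r)

    sig_ij = (siga[:, None] + sigb[None, :]) / 2.0
    eps_ij = np.sqrt(np.outer(epsa, epsb))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps_ij > 0, (sig_ij / r) ** 6, 0.0)
    vdw_pair = 4.0 * eps_ij * (sr6**2 - sr6)

    if model.cutoff is not None:
        # shifted potential: subtract the pair energy at the cutoff so the
        # truncated potential is continuous (zero) at r = cutoff
        within = r <= model.cutoff
        rc = model.cutoff
        if model.use_gb:
            f_gb_c = np.where(
                np.outer(borna, bornb) > 0,
                np.sqrt(rc**2 + np.outer(borna, bornb)
                        * np.exp(-(rc**2) / (4 * np.outer(borna, bornb)))),
                rc,
            )
            elec_c = qq * (
                1.0 / (model.eps_protein * rc)
                - (1.0 / model.eps_protein - 1.0 / model.eps_water) / f_gb_c
            )
        else:
            elec_c = qq / (model.eps_protein * rc)
        src6 = np.where(eps_ij > 0, (sig_ij / rc) ** 6, 0.0)
        vdw_c = 4.0 * eps_ij * (src6**2 - src6)
        elec_pair = np.where(within, elec_pair - elec_c, 0.0)
        vdw_pair = np.where(within, vdw_pair - vdw_c, 0.0)

    elec = float(elec_pair.sum())
    vdw = float(vdw_pair.sum())
    return elec + vdw, elec, vdw


def cluster_mean_enthalpy(
    topology: Topology,
    trajectory: Trajectory,
    clusters: list[Cluster],
    group_a: AtomSelection,
    group_b: AtomSelection,
    model: EnergyModel | None = None,
) -> EnergyReport:
    """Mean and sd of the inter-group interaction energy per cluster."""
    model = model or EnergyModel()
    report = EnergyReport()
    for cluster in clusters:
        members = np.asarray(cluster.member_frames, dtype=int)
        if len(members) == 0:
            logger.warning("cluster %d has no member frames; skipped", cluster.id)
            continue
        totals, elecs, vdws = [], [], []
        for f in members:
            tot, el, vw = pair_interaction_energy(
                topology, trajectory.coords[f], group_a, group_b, model,
                box=trajectory.frame_box(f),
            )
            totals.append(tot)
            elecs.append(el)
            vdws.append(vw)
        totals = np.array(totals)
        report.per_cluster[cluster.id] = {
            "mean": float(totals.mean()),
            "sd": float(totals.std(ddof=0)) if len(totals) > 1 else 0.0,
            "n_frames": int(len(members)),
            "elec": float(np.mean(elecs)),
            "vdw": float(np.mean(vdws)),
        }
    return report
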