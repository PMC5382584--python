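"""Orchestration: full trajectory analysis and assay analysis from a config.

``run_trajectory_analysis`` drives the whole chain — RMSD, rotation,
hydration, contacts, 2-D population map, clusters, per-cluster average
structures and interaction energies — from a single :class:`RunConfig`,
writing TSV/JSON/PDB outputs plus a manifest with input checksums.  The
``run_demo`` profiles generate synthetic reference systems with
literature-style state structure and push them through the same chain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic
from .structio import (
    Topology,
    Trajectory,
    read_pdb_models,
    read_param_table,
    apply_param_table,
    write_pdb_models,
    select,
)
from .geometry import (
    ScalarSeries,
    backbone_rmsd_series,
    helical_rotation_series,
)
from .observables import (
    HydrationSpec,
    ContactSpec,
    terminal_hydration_series,
    residue_contact_series,
)
from .population import (
    histogram2d,
    find_clusters,
    assign_frames,
    cluster_average_structure,
    clusters_to_json,
)
from .energetics import EnergyModel, cluster_mean_enthalpy

__all__ = ["RunConfig", "RunManifest", "run_trajectory_analysis", "run_demo",
           "DEMO_PROFILES"]

logger = logging.getLogger("groovescope")


@dataclass
class RunConfig:
    """All knobs of the trajectory pipeline, with the package defaults.

    Loadable from JSON via :meth:`from_json`; unset fields keep defaults so
    a config file only needs the entries it overrides.
    """

    trajectory_pdb: str = ""
    param_table: str = ""
    output_dir: str = "groovescope_out"
    dt: float = 0.1  # ns per frame when the PDB carries no times
    ligand_selection: str = "chain L and backbone"
    carrier_selection: str = "chain A or chain B"
    ligand_chain: str = "L"
    probe_residue: tuple[str, int] | None = None
    pocket_selection: str = ""
    hydration_cutoff: float = 5.0
    terminal_residue_count: int = 2
    contact_cutoff: float = 4.5
    rotation_bin_width: float = 2.0  # deg
    hydration_bin_width: float = 1.0  # waters
    distance_bin_width: float = 0.25  # A
    cluster_threshold: float = 0.10  # fraction of max bin count
    population_y: str = "hydration"  # "hydration" or "contact"
    eps_protein: float = 1.0
    eps_water: float = 78.5
    use_gb: bool = True
    energy_cutoff: float | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.probe_residue is not None:
            cfg.probe_residue = (str(cfg.probe_residue[0]), int(cfg.probe_residue[1]))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["probe_residue"] is not None:
            d["probe_residue"] = list(d["probe_residue"])
        return d


@dataclass
class RunManifest:
    """Record of a run: config echo, input checksums, outputs, stage status."""

    config: dict = field(default_factory=dict)
    version: str = ""
    input_checksums: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _analyze(
    topology: Topology,
    trajectory: Trajectory,
    config: RunConfig,
    out: Path,
    manifest: RunManifest,
) -> RunManifest:
    """Shared analysis chain for file-based and demo runs."""

    def stage(name):
        def mark(status):
            manifest.stages[name] = status
        return mark

    def emit(path: Path):
        manifest.outputs.append(str(path))

    lig_sel = select(topology, config.ligand_selection)
    car_sel = select(topology, config.carrier_selection)
    if len(lig_sel) == 0:
        raise ValueError(f"ligand selection {config.ligand_selection!r} is empty")
    if len(car_sel) == 0:
        raise ValueError(f"carrier selection {config.carrier_selection!r} is empty")

    # RMSD of the carrier backbone-equivalent after ligand alignment
    mark = stage("rmsd")
    rmsd = backbone_rmsd_series(
        topology, trajectory, lig_sel, car_sel, trajectory.coords[0]
    )
    rmsd.to_tsv(out / "rmsd.tsv")
    emit(out / "rmsd.tsv")
    mark("ok")

    mark = stage("rotation")
    rotation = helical_rotation_series(topology, trajectory, lig_sel, car_sel)
    rotation.to_tsv(out / "rotation.tsv")
    emit(out / "rotation.tsv")
    mark("ok")

    mark = stage("hydration")
    hydration = terminal_hydration_series(
        topology,
        trajectory,
        config.ligand_chain,
        HydrationSpec(
            terminal_residue_count=config.terminal_residue_count,
            cutoff=config.hydration_cutoff,
        ),
    )
    hydration.to_tsv(out / "hydration.tsv")
    emit(out / "hydration.tsv")
    mark("ok")

    contact_flags = None
    if config.probe_residue is not None and config.pocket_selection:
        mark = stage("contacts")
        pocket = select(topology, config.pocket_selection)
        contact_flags, contact_dist = residue_contact_series(
            topology,
            trajectory,
            ContactSpec(
                probe_residue=config.probe_residue,
                pocket_atoms=pocket,
                cutoff=config.contact_cutoff,
            ),
        )
        contact_flags.to_tsv(out / "contacts.tsv")
        contact_dist.to_tsv(out / "contact_distance.tsv")
        emit(out / "contacts.tsv")
        emit(out / "contact_distance.tsv")
        mark("ok")

    mark = stage("population")
    if config.population_y == "contact":
        if contact_flags is None:
            raise ValueError("population_y='contact' needs probe/pocket config")
        y_series, y_width = contact_flags, 1.0
    else:
        y_series, y_width = hydration, config.hydration_bin_width
    hist = histogram2d(rotation, y_series, config.rotation_bin_width, y_width)
    hist.to_tsv(out / "heatmap.tsv")
    emit(out / "heatmap.tsv")
    clusters = find_clusters(hist, config.cluster_threshold)
    assign_frames(clusters, rotation, y_series, hist)
    clusters_to_json(clusters, out / "clusters.json")
    emit(out / "clusters.json")
    mark("ok")

    mark = stage("average_structures")
    for cluster in clusters:
        avg = cluster_average_structure(topology, trajectory, cluster, lig_sel)
        path = out / f"cluster_{cluster.id}_avg.pdb"
        write_pdb_models(
            topology,
            Trajectory(coords=avg.coordinates[None, :, :], times=np.array([0.0])),
            path,
        )
        emit(path)
    mark("ok")

    mark = stage("energies")
    model = EnergyModel(
        eps_protein=config.eps_protein,
        eps_water=config.eps_water,
        use_gb=config.use_gb,
        cutoff=config.energy_cutoff,
    )
    lig_all = select(topology, f"chain {config.ligand_chain}")
    report = cluster_mean_enthalpy(
        topology, trajectory, clusters, car_sel, lig_all, model
    )
    with open(out / "energies.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    emit(out / "energies.json")
    mark("ok")

    manifest.write(out / "manifest.json")
    return manifest


def run_trajectory_analysis(config: RunConfig) -> RunManifest:
    """Run the full analysis chain on a multi-model PDB trajectory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=_version())
    if not config.trajectory_pdb:
        raise ValueError("config.trajectory_pdb is required")
    manifest.input_checksums[config.trajectory_pdb] = _sha256(config.trajectory_pdb)
    topology, trajectory = read_pdb_models(config.trajectory_pdb, dt=config.dt)
    if config.param_table:
        manifest.input_checksums[config.param_table] = _sha256(config.param_table)
        table = read_param_table(config.param_table)
        unmatched = apply_param_table(topology, table)
        if unmatched:
            logger.warning("%d atoms unmatched by parameter table", len(unmatched))
    try:
        return _analyze(topology, trajectory, config, out, manifest)
    except Exception:
        manifest.write(out / "manifest.json")
        raise


# ---------------------------------------------------------------------------
# demo profiles
# ---------------------------------------------------------------------------

def _demo_get3_like(seed: int):
    """Single dominant population: small rotation, low terminal hydration."""
    segments = [((0.0, 2), 0.0, 160.0)]
    rot, hyd = synthetic.make_cluster_schedule(segments, dt=0.5, seed=seed)
    spec = synthetic.TrajectorySpec(
        n_frames=len(rot), dt=0.5, rotation_schedule=rot,
        hydration_schedule=hyd, noise_sigma=0.05, seed=seed,
    )
    return spec, "hydration", segments


def _demo_arsa2_pep12_like(seed: int):
    """Four dwell states: drift to ~38 deg with groove closure, the largest
    state (low hydration, high rotation) holding ~31% of the frames."""
    segments = [
        ((0.0, 12), 0.0, 12.0),
        ((19.0, 7), 12.0, 61.5),
        ((39.0, 9), 61.5, 86.0),
        ((39.0, 2), 86.0, 136.0),   # dominant low-hydration/high-rotation state
        ((39.0, 9), 136.0, 160.0),
    ]
    rot, hyd = synthetic.make_cluster_schedule(segments, dt=0.5, seed=seed)
    spec = synthetic.TrajectorySpec(
        n_frames=len(rot), dt=0.5, rotation_schedule=rot,
        hydration_schedule=hyd, noise_sigma=0.05, seed=seed,
    )
    return spec, "hydration", segments


def _demo_arsa2_sec61b_like(seed: int):
    """Three states in the (rotation, contact) map: an early high-torsion
    meta-stable state, a rotated-back state, and a final docked state where
    the probe side chain sits in the induced pocket."""
    segments = [
        ((35.0, 3), 0.0, 93.5),
        ((3.0, 3), 93.5, 116.5),
        ((13.0, 3), 116.5, 160.0),
    ]
    rot, hyd = synthetic.make_cluster_schedule(segments, dt=0.5, seed=seed)
    n = len(rot)
    contact = np.zeros(n, dtype=bool)
    contact[int(round(116.5 / 0.5)):] = True
    spec = synthetic.TrajectorySpec(
        n_frames=n, dt=0.5, rotation_schedule=rot, hydration_schedule=hyd,
        contact_schedule=contact, noise_sigma=0.05, seed=seed,
    )
    return spec, "contact", segments


DEMO_PROFILES = {
    "get3_like": _demo_get3_like,
    "arsa2_pep12_like": _demo_arsa2_pep12_like,
    "arsa2_sec61b_like": _demo_arsa2_sec61b_like,
}


def run_demo(profile: str, output_dir: str | None = None, seed: int = 0) -> RunManifest:
    """Generate a named synthetic system and run the full analysis on it."""
    if profile not in DEMO_PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {sorted(DEMO_PROFILES)}"
        )
    spec, population_y, _segments = DEMO_PROFILES[profile](seed)
    topology, trajectory, _table = synthetic.make_complex_trajectory(spec)
    config = RunConfig(
        output_dir=output_dir or f"demo_{profile}",
        dt=spec.dt,
        population_y=population_y,
        probe_residue=synthetic.PROBE_RESIDUE,
        pocket_selection=synthetic.POCKET_SELECTION_EXPR,
        seed=seed,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=_version())
    manifest.config["demo_profile"] = profile
    synthetic.write_ground_truth(spec, out / "ground_truth.json")
    manifest.outputs.append(str(out / "ground_truth.json"))
    try:
        return _analyze(topology, trajectory, config, out, manifest)
    except Exception:
        manifest.write(out / "manifest.json")
        raise


def _version() -> str:
    from . import __version__

    return __version__
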