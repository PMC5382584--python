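"""2-D population analysis of paired trajectory observables.

Pairs of per-frame observables (e.g. helical rotation vs terminal hydration)
are binned into a 2-D histogram; high-occupancy bins form clusters
(8-connected components), which receive chronological indices, member
frames, occupancy percentages and dwell intervals.  Cluster-average
structures are computed after superposing member frames on a chosen
alignment selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structio import AtomSelection, Topology, Trajectory
from .geometry import ScalarSeries, kabsch_superpose

__all__ = [
    "Histogram2D",
    "Cluster",
    "AverageStructure",
    "histogram2d",
    "find_clusters",
    "assign_frames",
    "cluster_average_structure",
]


@dataclass
class Histogram2D:
    """Binned 2-D populations plus the bin each frame landed in.

    Bins are half-open, [edge, edge + width); edges start at
    floor(min / width) * width so equal data always lands in the same grid.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    frame_bins: np.ndarray  # (n_frames, 2) int bin indices per frame
    times: np.ndarray

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")
        if self.counts.sum() != len(self.frame_bins):
            raise ValueError("counts must sum to the number of binned frames")

    @property
    def n_frames(self) -> int:
        return len(self.frame_bins)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            (self.x_edges[:-1] + self.x_edges[1:]) / 2,
            (self.y_edges[:-1] + self.y_edges[1:]) / 2,
        )

    def to_tsv(self, path) -> None:
        """Write the count matrix with x bin centers as rows, y as columns."""
        xc, yc = self.bin_centers()
        with open(path, "w") as fh:
            fh.write("x_center\t" + "\t".join(f"{y:g}" for y in yc) + "\n")
            for i, x in enumerate(xc):
                fh.write(
                    f"{x:g}\t" + "\t".join(str(int(c)) for c in self.counts[i]) + "\n"
                )


@dataclass
class Cluster:
    """A connected high-occupancy region of the 2-D map.

    Indices are chronological: cluster 1 is the one whose earliest member
    frame comes first, matching the convention that cluster 1 is the initial
    state of the trajectory.
    """

    id: int
    bins: set
    centroid: tuple[float, float]
    member_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    occupancy_pct: float = 0.0
    dwell_intervals: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "n_bins": len(self.bins),
            "centroid": [float(self.centroid[0]), float(self.centroid[1])],
            "n_frames": int(len(self.member_frames)),
            "occupancy_pct": float(self.occupancy_pct),
            "dwell_intervals": [[float(a), float(b)] for a, b in self.dwell_intervals],
        }


@dataclass
class AverageStructure:
    coordinates: np.ndarray
    n_contributing: int
    alignment_selection: AtomSelection


def histogram2d(
    x: ScalarSeries, y: ScalarSeries, x_bin_width: float, y_bin_width: float
) -> Histogram2D:
    """Bin paired observables into half-open 2-D bins of the given widths."""
    if x_bin_width <= 0 or y_bin_width <= 0:
        raise ValueError("bin widths must be positive")
    if len(x) != len(y) or not np.allclose(x.times, y.times):
        raise ValueError("x and y series must share times")

    def edges(values: np.ndarray, width: float) -> np.ndarray:
        lo = math.floor(values.min() / width) * width
        hi = math.floor(values.max() / width) * width + width
        n = int(round((hi - lo) / width))
        return lo + np.arange(n + 1) * width

    x_edges = edges(x.values, x_bin_width)
    y_edges = edges(y.values, y_bin_width)
    # clip guards against one-ulp roundoff at the outermost edges
    ix = np.clip(
        np.floor((x.values - x_edges[0]) / x_bin_width).astype(int),
        0, len(x_edges) - 2,
    )
    iy = np.clip(
        np.floor((y.values - y_edges[0]) / y_bin_width).astype(int),
        0, len(y_edges) - 2,
    )
    counts = np.zeros((len(x_edges) - 1, len(y_edges) - 1), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    return Histogram2D(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        frame_bins=np.column_stack([ix, iy]),
        times=x.times.copy(),
    )


def find_clusters(hist: Histogram2D, occupancy_threshold: float = 0.10) -> list[Cluster]:
    """Extract 8-connected components of significant bins.

    A bin is significant when its count >= threshold * max(count).  Clusters
    are indexed chronologically by their earliest member frame (index 1 =
    earliest); the centroid is the count-weighted mean of bin centers.
    """
    if not 0 < occupancy_threshold <= 1:
        raise ValueError("occupancy_threshold must be in (0, 1]")
    if hist.counts.sum() == 0:
        raise ValueError("empty histogram")
    significant = hist.counts >= occupancy_threshold * hist.counts.max()
    labels, n_labels = ndimage.label(significant, structure=np.ones((3, 3), dtype=int))

    bin_label = {
        (i, j): labels[i, j]
        for i, j in zip(*np.nonzero(labels))
    }
    first_frame = {}
    for f, (i, j) in enumerate(hist.frame_bins):
        lab = bin_label.get((int(i), int(j)), 0)
        if lab and lab not in first_frame:
            first_frame[lab] = f
    # components never visited by a frame sort after all visited ones
    order = sorted(
        range(1, n_labels + 1), key=lambda lab: first_frame.get(lab, np.inf)
    )
    xc, yc = hist.bin_centers()
    clusters = []
    for new_id, lab in enumerate(order, start=1):
        ii, jj = np.nonzero(labels == lab)
        w = hist.counts[ii, jj].astype(float)
        centroid = (
            float((xc[ii] * w).sum() / w.sum()),
            float((yc[jj] * w).sum() / w.sum()),
        )
        clusters.append(
            Cluster(
                id=new_id,
                bins={(int(i), int(j)) for i, j in zip(ii, jj)},
                centroid=centroid,
            )
        )
    return clusters


def assign_frames(
    clusters: list[Cluster], x: ScalarSeries, y: ScalarSeries, hist: Histogram2D
) -> list[Cluster]:
    """Assign frames to the cluster owning their bin; fill occupancy and dwells.

    Frames whose bin belongs to no cluster stay unassigned.  Dwell intervals
    are maximal runs of consecutive assigned frames, reported as (time of
    first, time of last) in ns; a cluster may own several intervals.
    """
    if len(x) != hist.n_frames or not np.allclose(x.times, hist.times):
        raise ValueError("series do not match the histogram's frames")
    bin_owner = {}
    for c in clusters:
        for b in c.bins:
            bin_owner[b] = c.id
    n = hist.n_frames
    assignment = np.zeros(n, dtype=int)  # 0 = unassigned
    for f, (i, j) in enumerate(hist.frame_bins):
        assignment[f] = bin_owner.get((int(i), int(j)), 0)

    times = hist.times
    for c in clusters:
        members = np.nonzero(assignment == c.id)[0]
        c.member_frames = members
        c.occupancy_pct = 100.0 * len(members) / n
        intervals = []
        if len(members):
            run_start = members[0]
            prev = members[0]
            for f in members[1:]:
                if f != prev + 1:
                    intervals.append((float(times[run_start]), float(times[prev])))
                    run_start = f
                prev = f
            intervals.append((float(times[run_start]), float(times[prev])))
        c.dwell_intervals = intervals
    return clusters


def cluster_average_structure(
    topology: Topology,
    trajectory: Trajectory,
    cluster: Cluster,
    alignment_selection: AtomSelection,
) -> AverageStructure:
    """Mean coordinates over member frames after superposition.

    Every member frame is superposed onto the first member frame using the
    alignment selection (mass-weighted), then the unweighted coordinate mean
    over members is taken.
    """
    members = np.asarray(cluster.member_frames, dtype=int)
    if len(members) == 0:
        raise ValueError(f"cluster {cluster.id} has no member frames")
    masses = topology.masses()
    sel = alignment_selection.indices
    ref = trajectory.coords[members[0]]
    total = np.zeros((trajectory.n_atoms, 3))
    for f in members:
        frame = trajectory.coords[f]
        transform, _ = kabsch_superpose(frame[sel], ref[sel], masses[sel])
        total += transform.apply(frame)
    return AverageStructure(
        coordinates=total / len(members),
        n_contributing=len(members),
        alignment_selection=alignment_selection,
    )


def clusters_to_json(clusters: list[Cluster], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in clusters], fh, indent=2)
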