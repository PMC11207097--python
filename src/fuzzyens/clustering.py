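"""Oligomer identification by contact connectivity in periodic boxes.

Two molecules belong to the same oligomer (cluster) in a frame when they make
at least one inter-molecular residue contact (0.7 nm minimum-bead distance,
minimum image — the same rule as the contacts module).  Starting from
singleton clusters, clusters are merged whenever any molecule of one touches
any molecule of the other, until no merge applies; the fixed point is the set
of connected components of the molecule contact graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._distances import cross_min_distances
from .contacts import DEFAULT_CUTOFF
from .ensemble import ConformationFrame, Ensemble


@dataclass(frozen=True)
class ClusterPartition:
    """Partition of molecule indices into oligomeric clusters (one frame)."""

    clusters: tuple[frozenset[int], ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def largest_size(self) -> int:
        return max(len(c) for c in self.clusters)

    def cluster_of(self, molecule: int) -> frozenset[int]:
        for c in self.clusters:
            if molecule in c:
                return c
        raise KeyError(f"molecule {molecule} not in partition")


def molecule_contact_graph(
    frame: ConformationFrame, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Boolean molecule–molecule adjacency: any residue contact between them."""
    top = frame.topology
    n = top.n_molecules
    adj = np.zeros((n, n), dtype=bool)
    for ma, mb in combinations(range(n), 2):
        d = cross_min_distances(
            frame.molecule_coords(ma),
            top.molecules[ma],
            frame.molecule_coords(mb),
            top.molecules[mb],
            box_edge=frame.box_edge,
        )
        if (d < cutoff).any():
            adj[ma, mb] = adj[mb, ma] = True
    return adj


def frame_clusters(
    frame: ConformationFrame, cutoff: float = DEFAULT_CUTOFF
) -> ClusterPartition:
    """Agglomerative clustering of the molecules of one frame.

    Each molecule starts as its own cluster; two clusters merge when any
    molecule of one is in contact with any molecule of the other, repeated
    until no merge applies.
    """
    top = frame.topology
    n = top.n_molecules
    if n < 2:
        import warnings

        warnings.warn("single-molecule frame: trivial partition", stacklevel=2)
        return ClusterPartition(clusters=(frozenset({0}),))
    if frame.box_edge is None:
        raise ValueError("clustering requires a periodic box edge")
    adj = molecule_contact_graph(frame, cutoff)
    clusters: list[set[int]] = [{m} for m in range(n)]
    merged = True
    while merged:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if any(adj[i, j] for i in clusters[a] for j in clusters[b]):
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    merged = True
                    break
            if merged:
                break
    ordered = tuple(
        frozenset(c) for c in sorted(clusters, key=lambda c: min(c))
    )
    return ClusterPartition(clusters=ordered)


@dataclass
class ClusterSeries:
    """Per-frame cluster statistics and their normalised histograms."""

    n_clusters: np.ndarray
    largest_size: np.ndarray
    n_molecules: int
    hist_n_clusters: np.ndarray = field(repr=False)  # P(n_clusters = 1..M)
    hist_largest: np.ndarray = field(repr=False)  # P(largest = 1..M)

    @property
    def p_all_in_one(self) -> float:
        """Probability that all molecules form a single cluster."""
        return float(self.hist_n_clusters[0])


def cluster_series(ensemble: Ensemble, cutoff: float = DEFAULT_CUTOFF) -> ClusterSeries:
    """Cluster statistics over a trajectory (counts normalised to 1)."""
    m = ensemble.topology.n_molecules
    n_clusters = np.empty(ensemble.n_frames, dtype=int)
    largest = np.empty(ensemble.n_frames, dtype=int)
    for k, frame in enumerate(ensemble):
        part = frame_clusters(frame, cutoff)
        n_clusters[k] = part.n_clusters
        largest[k] = part.largest_size
    bins = np.arange(0.5, m + 1.5)
    hist_n = np.histogram(n_clusters, bins=bins)[0] / ensemble.n_frames
    hist_l = np.histogram(largest, bins=bins)[0] / ensemble.n_frames
    return ClusterSeries(
        n_clusters=n_clusters,
        largest_size=largest,
        n_molecules=m,
        hist_n_clusters=hist_n,
        hist_largest=hist_l,
    )
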