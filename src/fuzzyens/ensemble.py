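"""Conformational ensembles: ordered frames of bead coordinates over a topology.

Coordinates are stored in nanometres throughout.  Frames may carry a cubic
box edge (needed for inter-molecular analyses under periodic boundary
conditions) and a time stamp in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TopologyError
from .topology import BeadTopology


@dataclass
class ConformationFrame:
    """One conformation: bead coordinates (nm), optional cubic box edge (nm)."""

    topology: BeadTopology
    coords: np.ndarray  # (n_beads_total, 3), nm
    box_edge: float | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TopologyError("frame coordinates must have shape (n_beads, 3)")
        if self.coords.shape[0] != self.topology.n_beads_total:
            raise TopologyError(
                f"frame has {self.coords.shape[0]} beads, topology expects "
                f"{self.topology.n_beads_total}"
            )
        if self.box_edge is not None and not self.box_edge > 0:
            raise TopologyError("box edge must be positive when present")

    def molecule_coords(self, molecule: int) -> np.ndarray:
        return self.coords[self.topology.molecule_bead_slice(molecule)]


class Ensemble:
    """Ordered conformations over a shared topology.

    Internally a dense ``(N, n_beads, 3)`` float array for vectorised
    analysis; :meth:`frame` materialises individual
    :class:`ConformationFrame` views.
    """

    def __init__(
        self,
        topology: BeadTopology,
        xyz: np.ndarray,
        box_edge: float | np.ndarray | None = None,
        times: np.ndarray | None = None,
    ):
        xyz = np.asarray(xyz, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise TopologyError("ensemble coordinates must have shape (N, n_beads, 3)")
        if xyz.shape[0] < 1:
            raise TopologyError("ensemble needs at least one frame")
        if xyz.shape[1] != topology.n_beads_total:
            raise TopologyError(
                f"frames have {xyz.shape[1]} beads, topology expects "
                f"{topology.n_beads_total} (first offending frame: 0)"
            )
        self.topology = topology
        self.xyz = xyz
        if box_edge is None:
            self.box_edges = None
        else:
            be = np.broadcast_to(np.asarray(box_edge, dtype=float), (xyz.shape[0],))
            if not (be > 0).all():
                raise TopologyError("box edges must be positive")
            self.box_edges = np.array(be)
        self.times = None if times is None else np.asarray(times, dtype=float)

    # -- container protocol ---------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> ConformationFrame:
        return ConformationFrame(
            topology=self.topology,
            coords=self.xyz[i],
            box_edge=None if self.box_edges is None else float(self.box_edges[i]),
            time=None if self.times is None else float(self.times[i]),
        )

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    # -- convenience -----------------------------------------------------
    def molecule_xyz(self, molecule: int) -> np.ndarray:
        """Coordinates of one molecule across all frames, shape (N, B_mol, 3)."""
        return self.xyz[:, self.topology.molecule_bead_slice(molecule), :]

    def backbone_xyz(self, molecule: int = 0) -> np.ndarray:
        """Backbone-bead coordinates, shape (N, n_residues, 3)."""
        sl = self.topology.molecule_bead_slice(molecule)
        bb = self.topology.molecules[molecule].backbone_beads + sl.start
        return self.xyz[:, bb, :]


def stride(ensemble: Ensemble, k: int) -> Ensemble:
    """Keep every ``k``-th frame (indices 0, k, 2k, ...).

    The output frame count is ``ceil(N / k)``; ``k=1`` is the identity.
    """
    if k < 1:
        raise ValueError("stride must be >= 1")
    sel = slice(None, None, k)
    return Ensemble(
        ensemble.topology,
        ensemble.xyz[sel],
        box_edge=None if ensemble.box_edges is None else ensemble.box_edges[sel],
        times=None if ensemble.times is None else ensemble.times[sel],
    )
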