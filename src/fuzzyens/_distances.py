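"""Internal distance kernels: residue-level minimum-bead distances.

The residue–residue distance d_ij used by the scaling and contact analyses is
the smallest of all bead–bead distances between the beads of residue i and
residue j.  Beads of a residue are contiguous in the coordinate array, so the
bead-level distance matrix reduces to residue blocks with two
``np.minimum.reduceat`` passes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .topology import MoleculeTopology


def _block_min(d: np.ndarray, row_offsets: np.ndarray, col_offsets: np.ndarray) -> np.ndarray:
    """Reduce a bead-pair distance matrix to per-residue-block minima."""
    d = np.minimum.reduceat(d, row_offsets[:-1], axis=0)
    d = np.minimum.reduceat(d, col_offsets[:-1], axis=1)
    return d


def residue_min_distances(coords: np.ndarray, mol: MoleculeTopology) -> np.ndarray:
    """(n_res, n_res) matrix of minimum bead–bead distances within a molecule."""
    d = cdist(coords, coords)
    return _block_min(d, mol.bead_offsets, mol.bead_offsets)


def minimum_image_diffs(xa: np.ndarray, xb: np.ndarray, box_edge: float) -> np.ndarray:
    """Pairwise displacement vectors xa[i] - xb[j] under the minimum-image
    convention in a cubic box, shape (len(xa), len(xb), 3)."""
    diff = xa[:, None, :] - xb[None, :, :]
    diff -= box_edge * np.round(diff / box_edge)
    return diff


def cross_min_distances(
    coords_a: np.ndarray,
    mol_a: MoleculeTopology,
    coords_b: np.ndarray,
    mol_b: MoleculeTopology,
    box_edge: float | None = None,
) -> np.ndarray:
    """(n_res_a, n_res_b) minimum bead–bead distances between two molecules.

    With ``box_edge`` set, bead displacements use the minimum-image
    convention (inter-molecular geometry in a periodic box).
    """
    if box_edge is None:
        d = cdist(coords_a, coords_b)
    else:
        d = np.linalg.norm(minimum_image_diffs(coords_a, coords_b, box_edge), axis=2)
    return _block_min(d, mol_a.bead_offsets, mol_b.bead_offsets)
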