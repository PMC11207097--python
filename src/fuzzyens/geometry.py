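"""Per-conformation size metrics and block-averaged error estimates.

Metrics follow the usual conventions for coarse-grained protein ensembles:

* ``Rg`` — root-mean-square distance of all of a molecule's beads from their
  centroid (unweighted by default; per-bead weights optional).
* ``Dmax`` — the largest distance over all bead pairs (exhaustive search).
* ``dee`` — distance between the backbone beads of the first and the last
  residue (the N-to-C end-to-end distance).

Statistical errors of trajectory averages come from block error analysis:
the series is cut into contiguous blocks and the standard error of the block
means is tracked as the block size grows; for a correlated series it rises
to a plateau that estimates the true error of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .ensemble import ConformationFrame, Ensemble
from .errors import TopologyError


def _molecule_coords(frame: ConformationFrame, molecule: int) -> np.ndarray:
    return frame.molecule_coords(molecule)


def radius_of_gyration(
    frame: ConformationFrame, molecule: int = 0, weights: np.ndarray | None = None
) -> float:
    """Radius of gyration of one molecule in one frame (nm)."""
    x = _molecule_coords(frame, molecule)
    if weights is None:
        w = np.full(x.shape[0], 1.0 / x.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (x.shape[0],) or w.sum() <= 0:
            raise ValueError("weights must be positive with one entry per bead")
        w = w / w.sum()
    centroid = w @ x
    return float(np.sqrt(np.sum(w * np.sum((x - centroid) ** 2, axis=1))))


def max_diameter(frame: ConformationFrame, molecule: int = 0) -> float:
    """Maximum bead-pair distance of one molecule (nm); 0 for a single bead."""
    x = _molecule_coords(frame, molecule)
    if x.shape[0] < 2:
        import warnings

        warnings.warn("max_diameter of a single-bead molecule is 0", stacklevel=2)
        return 0.0
    return float(pdist(x).max())


def end_to_end(frame: ConformationFrame, molecule: int = 0) -> float:
    """N-to-C backbone-bead distance of one molecule (nm)."""
    mol = frame.topology.molecules[molecule]
    sl = frame.topology.molecule_bead_slice(molecule)
    if mol.backbone_beads.size < 1:
        raise TopologyError("molecule has no backbone beads designated")
    first = frame.coords[sl.start + mol.backbone_beads[0]]
    last = frame.coords[sl.start + mol.backbone_beads[-1]]
    return float(np.linalg.norm(last - first))


@dataclass
class ConformerMetrics:
    """Per-frame Rg / Dmax / dee series for one molecule (all nm)."""

    rg: np.ndarray
    dmax: np.ndarray
    dee: np.ndarray


def metrics_series(ensemble: Ensemble, molecule: int = 0) -> ConformerMetrics:
    """Rg, Dmax and dee for every frame (vectorised where possible)."""
    x = ensemble.molecule_xyz(molecule)  # (N, B, 3)
    centroid = x.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((x - centroid) ** 2, axis=2), axis=1))
    bb = ensemble.backbone_xyz(molecule)
    dee = np.linalg.norm(bb[:, -1, :] - bb[:, 0, :], axis=1)
    if x.shape[1] < 2:
        dmax = np.zeros(x.shape[0])
    else:
        dmax = np.array([pdist(x[i]).max() for i in range(x.shape[0])])
    return ConformerMetrics(rg=rg, dmax=dmax, dee=dee)


# ---------------------------------------------------------------------------
# block error analysis
# ---------------------------------------------------------------------------


@dataclass
class SeriesSummary:
    """Mean, block-error estimate and normalised histogram of a series."""

    mean: float
    error: float  # block-error plateau (largest block size by default)
    block_sizes: np.ndarray = field(repr=False)
    block_errors: np.ndarray = field(repr=False)
    hist_edges: np.ndarray = field(repr=False)
    hist_density: np.ndarray = field(repr=False)


def block_error(
    series: np.ndarray,
    block_sizes: np.ndarray | None = None,
    bins: int = 50,
) -> SeriesSummary:
    """Block error analysis of a (possibly correlated) scalar series.

    For each block size the series is cut into ``n // size`` contiguous
    blocks (a trailing remainder is dropped) and the standard error of the
    block means is recorded.  The reported ``error`` is the value at the
    largest block size, where the estimate has plateaued for series much
    longer than the correlation time.
    """
    y = np.asarray(series, dtype=float).ravel()
    n = y.size
    if block_sizes is None:
        # powers of two, keeping >= 32 blocks at the largest size so the
        # plateau estimate itself has usable precision (~1/sqrt(2*31) rel.)
        if n < 8:
            raise ValueError("series too short for block error analysis (need >= 8)")
        largest = max(n // 64, 2)
        sizes = 2 ** np.arange(0, int(np.log2(largest)) + 1)
    else:
        sizes = np.asarray(block_sizes, dtype=int)
        if sizes.size == 0 or (sizes < 1).any():
            raise ValueError("block sizes must be positive")
        if n < 4 * sizes.max():
            raise ValueError(
                f"series of length {n} too short for max block size {sizes.max()} "
                "(need length >= 4 * max block size)"
            )
    errs = np.empty(sizes.size)
    for k, size in enumerate(sizes):
        nb = n // size
        means = y[: nb * size].reshape(nb, size).mean(axis=1)
        if nb < 2 or np.ptp(means) == 0.0:
            errs[k] = 0.0
        else:
            errs[k] = means.std(ddof=1) / np.sqrt(nb)
    lo, hi = y.min(), y.max()
    if hi == lo:
        hi = lo + 1.0  # degenerate constant series: arbitrary unit-width bin
    density, edges = np.histogram(y, bins=bins, range=(lo, hi), density=True)
    return SeriesSummary(
        mean=float(y.mean()),
        error=float(errs[-1]),
        block_sizes=sizes,
        block_errors=errs,
        hist_edges=edges,
        hist_density=density,
    )
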