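"""Residue contact statistics for fuzzy intra- and inter-molecular interactions.

Two residues are in contact in a frame when the smallest distance between any
bead of one and any bead of the other is below a cutoff (default 0.7 nm).
Within a molecule, pairs closer than ``n_neighbors_ignored`` (default 3) in
sequence — (i, i+1), (i, i+2), (i, i+3) — are excluded; across molecules every
pair is eligible and bead distances use the minimum-image convention in the
cubic box.

Contact probabilities are frame fractions; their errors come from block
averaging over the trajectory.  Map comparison runs a per-pair one-way ANOVA
on the block means of the two ensembles, the natural replicate structure for
correlated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from ._distances import cross_min_distances, residue_min_distances
from .ensemble import ConformationFrame, Ensemble
from .errors import TopologyError

DEFAULT_CUTOFF = 0.7  # nm
DEFAULT_NEIGHBORS_IGNORED = 3


# ---------------------------------------------------------------------------
# per-frame contacts
# ---------------------------------------------------------------------------


def _intra_pairs(n_res: int, n_neighbors_ignored: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n_res, k=n_neighbors_ignored + 1)
    return iu, ju


def frame_contacts(
    frame: ConformationFrame,
    scope: str = "intra",
    cutoff: float = DEFAULT_CUTOFF,
    n_neighbors_ignored: int = DEFAULT_NEIGHBORS_IGNORED,
    molecule: int = 0,
):
    """Residue pairs in contact in one frame.

    ``scope="intra"`` examines one molecule (``molecule``) and returns a set
    of 1-based residue pairs ``(i, j)`` with ``i < j`` and ``j - i >
    n_neighbors_ignored``.  ``scope="inter"`` examines all molecule pairs and
    returns a set of ``((mol_a, i), (mol_b, j))`` with ``mol_a < mol_b``;
    sequence exclusions do not apply across molecules, and distances use the
    minimum image in the frame's cubic box.
    """
    top = frame.topology
    if scope == "intra":
        mol = top.molecules[molecule]
        d = residue_min_distances(frame.molecule_coords(molecule), mol)
        iu, ju = _intra_pairs(mol.n_residues, n_neighbors_ignored)
        hit = d[iu, ju] < cutoff
        return {(int(i) + 1, int(j) + 1) for i, j in zip(iu[hit], ju[hit])}
    if scope == "inter":
        if top.n_molecules < 2:
            raise ValueError("inter scope requires at least two molecules")
        if frame.box_edge is None:
            raise ValueError("inter scope requires a box edge (periodic box)")
        out = set()
        for ma, mb in combinations(range(top.n_molecules), 2):
            d = cross_min_distances(
                frame.molecule_coords(ma),
                top.molecules[ma],
                frame.molecule_coords(mb),
                top.molecules[mb],
                box_edge=frame.box_edge,
            )
            ii, jj = np.nonzero(d < cutoff)
            out.update(((ma, int(i) + 1), (mb, int(j) + 1)) for i, j in zip(ii, jj))
        return out
    raise ValueError(f"scope must be 'intra' or 'inter', got {scope!r}")


# ---------------------------------------------------------------------------
# trajectory-level boolean contact tensors
# ---------------------------------------------------------------------------


def _intra_contact_bool(
    ensemble: Ensemble, molecule: int, cutoff: float, n_neighbors_ignored: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(N, n_pairs) boolean matrix over the included intra pairs."""
    mol = ensemble.topology.molecules[molecule]
    iu, ju = _intra_pairs(mol.n_residues, n_neighbors_ignored)
    out = np.empty((ensemble.n_frames, iu.size), dtype=bool)
    xyz = ensemble.molecule_xyz(molecule)
    for k in range(ensemble.n_frames):
        d = residue_min_distances(xyz[k], mol)
        out[k] = d[iu, ju] < cutoff
    return out, iu, ju


def _inter_contact_bool(
    ensemble: Ensemble, cutoff: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(N, n_pairs) booleans over residue pairs (i, j): contact between
    residue i of any molecule and residue j of any *other* molecule.

    Symmetrised over molecule orderings, so the pair list covers i <= j.
    """
    top = ensemble.topology
    if top.n_molecules < 2:
        raise ValueError("inter scope requires at least two molecules")
    if ensemble.box_edges is None:
        raise ValueError("inter scope requires box edges")
    n_res = top.molecules[0].n_residues
    iu, ju = np.triu_indices(n_res, k=0)
    out = np.zeros((ensemble.n_frames, iu.size), dtype=bool)
    for k in range(ensemble.n_frames):
        frame = ensemble.frame(k)
        hit = np.zeros((n_res, n_res), dtype=bool)
        for ma, mb in combinations(range(top.n_molecules), 2):
            d = cross_min_distances(
                frame.molecule_coords(ma),
                top.molecules[ma],
                frame.molecule_coords(mb),
                top.molecules[mb],
                box_edge=frame.box_edge,
            )
            c = d < cutoff
            hit |= c
            hit |= c.T
        out[k] = hit[iu, ju]
    return out, iu, ju


def _contact_bool(
    ensemble: Ensemble,
    scope: str,
    cutoff: float,
    n_neighbors_ignored: int,
    molecule: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if scope == "intra":
        return _intra_contact_bool(ensemble, molecule, cutoff, n_neighbors_ignored)
    if scope == "inter":
        return _inter_contact_bool(ensemble, cutoff)
    raise ValueError(f"scope must be 'intra' or 'inter', got {scope!r}")


# ---------------------------------------------------------------------------
# contact probability maps
# ---------------------------------------------------------------------------


def _block_means(bools: np.ndarray, n_blocks: int) -> np.ndarray:
    """Contiguous block means over frames, shape (n_blocks, n_pairs)."""
    n = bools.shape[0]
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n_blocks = min(n_blocks, n)
    size = n // n_blocks
    trimmed = bools[: size * n_blocks].astype(float)
    return trimmed.reshape(n_blocks, size, -1).mean(axis=1)


@dataclass
class ContactMap:
    """Residue-pair contact probabilities with block errors.

    Pairs are stored condensed over the included (i, j) index arrays
    (0-based); :meth:`matrix` materialises the symmetric dense map with NaN
    at excluded near-diagonal entries.
    """

    n_residues: int
    i_idx: np.ndarray = field(repr=False)
    j_idx: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    error: np.ndarray = field(repr=False)
    block_means: np.ndarray = field(repr=False)
    scope: str = "intra"
    n_frames: int = 0

    def matrix(self) -> np.ndarray:
        m = np.full((self.n_residues, self.n_residues), np.nan)
        m[self.i_idx, self.j_idx] = self.p
        m[self.j_idx, self.i_idx] = self.p
        return m

    def probability(self, i: int, j: int) -> float:
        """Contact probability for 1-based residues (i, j)."""
        a, b = min(i, j) - 1, max(i, j) - 1
        sel = (self.i_idx == a) & (self.j_idx == b)
        if not sel.any():
            raise KeyError(f"pair ({i}, {j}) not in map (excluded or out of range)")
        return float(self.p[sel][0])


def contact_probability_map(
    ensemble: Ensemble,
    scope: str = "intra",
    cutoff: float = DEFAULT_CUTOFF,
    n_neighbors_ignored: int = DEFAULT_NEIGHBORS_IGNORED,
    molecule: int = 0,
    n_blocks: int = 10,
) -> ContactMap:
    """Contact frequencies over the trajectory, with block errors.

    The probability of a pair is the number of frames in which it is in
    contact divided by the total number of frames.  Errors are standard
    errors of the ``n_blocks`` contiguous block means.
    """
    bools, iu, ju = _contact_bool(ensemble, scope, cutoff, n_neighbors_ignored, molecule)
    p = bools.mean(axis=0)
    bm = _block_means(bools, n_blocks)
    nb = bm.shape[0]
    err = bm.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros(p.size)
    return ContactMap(
        n_residues=ensemble.topology.molecules[molecule].n_residues,
        i_idx=iu,
        j_idx=ju,
        p=p,
        error=err,
        block_means=bm,
        scope=scope,
        n_frames=ensemble.n_frames,
    )


# ---------------------------------------------------------------------------
# domain-level profiles
# ---------------------------------------------------------------------------


@dataclass
class DomainContactProfile:
    """Residue-vs-domain and domain-vs-domain contact probabilities.

    ``residue_profiles[D][i-1]`` is the fraction of frames in which residue i
    contacts at least one residue of domain D (p_i(D) intra, pi_i(D) inter);
    ``strand_profiles[(S, D)]`` the fraction of frames in which any residue
    of strand S contacts domain D; ``domain_matrix[(D1, D2)]`` the fraction
    of frames with at least one D1–D2 contact, with its block error.
    """

    scope: str
    domains: list[str]
    residue_profiles: dict[str, np.ndarray]
    residue_errors: dict[str, np.ndarray]
    strand_profiles: dict[tuple[str, str], float]
    domain_matrix: dict[tuple[str, str], tuple[float, float]]


def _union_series(bools: np.ndarray, iu, ju, rows_mask, cols_mask) -> np.ndarray:
    """Per-frame indicator that any included pair links rows_mask to cols_mask."""
    sel = (rows_mask[iu] & cols_mask[ju]) | (rows_mask[ju] & cols_mask[iu])
    if not sel.any():
        return np.zeros(bools.shape[0], dtype=bool)
    return bools[:, sel].any(axis=1)


def domain_profile(
    ensemble: Ensemble,
    scope: str = "intra",
    cutoff: float = DEFAULT_CUTOFF,
    n_neighbors_ignored: int = DEFAULT_NEIGHBORS_IGNORED,
    molecule: int = 0,
    n_blocks: int = 10,
) -> DomainContactProfile:
    """Residue-, strand- and domain-level contact probabilities.

    Uses the topology's domain and strand annotation; contact determination
    (cutoff, sequence exclusions, minimum image for inter scope) is identical
    to :func:`frame_contacts`.
    """
    top = ensemble.topology
    if not top.domains:
        raise TopologyError("topology has no domain annotation")
    n_res = top.molecules[molecule].n_residues
    bools, iu, ju = _contact_bool(ensemble, scope, cutoff, n_neighbors_ignored, molecule)

    domain_masks = {}
    for name in top.domains:
        mask = np.zeros(n_res, dtype=bool)
        mask[top.domain_residues(name) - 1] = True
        domain_masks[name] = mask

    residue_profiles: dict[str, np.ndarray] = {}
    residue_errors: dict[str, np.ndarray] = {}
    for name, dmask in domain_masks.items():
        series = np.zeros((ensemble.n_frames, n_res), dtype=bool)
        # residue i in contact with any residue of domain D in each frame
        touch = dmask[ju]
        touch_rev = dmask[iu]
        for i in range(n_res):
            sel = ((iu == i) & touch) | ((ju == i) & touch_rev)
            if sel.any():
                series[:, i] = bools[:, sel].any(axis=1)
        residue_profiles[name] = series.mean(axis=0)
        bm = _block_means(series, n_blocks)
        nb = bm.shape[0]
        residue_errors[name] = (
            bm.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros(n_res)
        )

    strand_profiles: dict[tuple[str, str], float] = {}
    for sname in top.strands:
        smask = np.zeros(n_res, dtype=bool)
        smask[top.strand_residues(sname) - 1] = True
        for dname, dmask in domain_masks.items():
            strand_profiles[(sname, dname)] = float(
                _union_series(bools, iu, ju, smask, dmask).mean()
            )

    domain_matrix: dict[tuple[str, str], tuple[float, float]] = {}
    names = sorted(top.domains)
    for a in names:
        for b in names:
            if names.index(b) < names.index(a):
                continue
            series = _union_series(bools, iu, ju, domain_masks[a], domain_masks[b])
            bm = _block_means(series[:, None], n_blocks)
            nb = bm.shape[0]
            err = float(bm.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
            domain_matrix[(a, b)] = (float(series.mean()), err)

    return DomainContactProfile(
        scope=scope,
        domains=names,
        residue_profiles=residue_profiles,
        residue_errors=residue_errors,
        strand_profiles=strand_profiles,
        domain_matrix=domain_matrix,
    )


# ---------------------------------------------------------------------------
# map comparison (ANOVA on block means)
# ---------------------------------------------------------------------------


@dataclass
class MapComparison:
    """Per-pair |Δp|, ANOVA p-values and nested significance masks."""

    i_idx: np.ndarray
    j_idx: np.ndarray
    delta: np.ndarray
    p_values: np.ndarray
    masks: dict[float, np.ndarray]
    min_delta: float

    def n_significant(self, threshold: float) -> int:
        return int(self.masks[threshold].sum())


def compare_maps(
    map_a: ContactMap,
    map_b: ContactMap,
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.005),
    min_delta: float = 0.001,
) -> MapComparison:
    """Compare two contact maps pair by pair.

    For every residue pair a one-way ANOVA is run on the stored block means
    of the two ensembles (blocks as replicates).  A pair is flagged at a
    threshold when its ANOVA p-value falls below the threshold *and*
    |Δp| > ``min_delta``; masks at decreasing thresholds are nested.
    """
    if map_a.n_residues != map_b.n_residues or map_a.i_idx.size != map_b.i_idx.size:
        raise ValueError("maps must share the same residue-pair structure")
    ga, gb = map_a.block_means, map_b.block_means
    na, nb = ga.shape[0], gb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 blocks per ensemble for the ANOVA")
    ma, mb = ga.mean(axis=0), gb.mean(axis=0)
    grand = (na * ma + nb * mb) / (na + nb)
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ((ga - ma) ** 2).sum(axis=0) + ((gb - mb) ** 2).sum(axis=0)
    df_within = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ss_between / (ss_within / df_within)
        p_values = stats.f.sf(f_stat, 1, df_within)
    # degenerate pairs: no within-group variance
    zero_w = ss_within == 0
    p_values[zero_w & (ss_between > 0)] = 0.0
    p_values[zero_w & (ss_between == 0)] = 1.0
    delta = np.abs(map_a.p - map_b.p)
    masks = {
        thr: (p_values < thr) & (delta > min_delta) for thr in thresholds
    }
    return MapComparison(
        i_idx=map_a.i_idx,
        j_idx=map_a.j_idx,
        delta=delta,
        p_values=p_values,
        masks=masks,
        min_delta=min_delta,
    )
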