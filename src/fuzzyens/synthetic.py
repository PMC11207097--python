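"""Seeded synthetic-ensemble generators.

These generators stand in for coarse-grained MD trajectories: they produce
ensembles with the statistical structure the analysis modules assume, with
every source of randomness controlled by an integer seed (bitwise-identical
repeat runs).

* :func:`generate_fjc` — freely jointed chain, the ideal-chain reference for
  which the closed forms <R_ee^2> = (n-1) b^2 and <Rg^2> = (n-1) b^2 / 6
  (large n) hold.
* :func:`generate_solvent_chain` — Metropolis Monte Carlo of a fixed-bond
  bead chain with a short-range pairwise square well.  The well depth
  ``pair_well`` plays the role of a solvent-quality knob: attraction
  (negative values) collapses the chain (nu < 1/2), a purely repulsive core
  swells it (nu > 1/2), and the ideal limit (no core, no well) reproduces
  the freely jointed chain exactly.  The mapping to any particular
  force-field rescaling is qualitative by design.
* :func:`sample_gaussian_dee` — i.i.d. draws from the Gaussian-chain
  end-to-end distance density with scale xi.
* :func:`generate_two_domain` — a rigid folded domain tethered to a flexible
  tail (the disordered-tail + folded-domain architecture of galectin-3).
* :func:`generate_box` — several molecules packed at random positions and
  orientations into a periodic cubic box with a minimum-separation tolerance.
* :func:`generate_reference_saxs` — a noisy affine transform of a model
  scattering curve, emulating an experimental reference dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from ._distances import minimum_image_diffs
from .ensemble import Ensemble
from .errors import PackingError
from .saxs import ScatteringProfile
from .topology import BeadTopology, simple_chain_topology, two_domain_topology

DEFAULT_BOND_LENGTH = 0.55  # nm, the Kuhn length used for IDP scaling fits

#: Outer radius of the pairwise square well, in units of the bond length.
WELL_RANGE_FACTOR = 1.5


@dataclass
class ChainSpec:
    """Parameters of a synthetic bead-spring chain.

    ``pair_well`` is the dimensionless solvent-quality knob (in kT): negative
    values switch on a short-range attraction of that depth, zero or positive
    leaves only the repulsive core of radius ``excluded_radius`` (0 disables
    it, giving an ideal chain).  ``sweeps`` is the number of Monte Carlo
    sweeps between saved frames.
    """

    n_residues: int
    bond_length: float = DEFAULT_BOND_LENGTH  # nm
    excluded_radius: float = 0.0  # nm, hard-core diameter (0 = none)
    pair_well: float = 0.0  # kT; negative = attraction
    sweeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if not self.bond_length > 0:
            raise ValueError("bond_length must be positive")
        if self.excluded_radius < 0:
            raise ValueError("excluded_radius must be >= 0")


@dataclass
class BoxSpec:
    """Parameters of a periodic cubic box of several molecules."""

    box_edge: float = 20.0  # nm
    n_molecules: int = 6
    tolerance: float = 0.4  # nm, minimum inter-molecular bead separation
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


# ---------------------------------------------------------------------------
# freely jointed chain
# ---------------------------------------------------------------------------


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_fjc(
    spec: ChainSpec, n_frames: int, topology: BeadTopology | None = None
) -> Ensemble:
    """Freely jointed chain: independent frames, uniform bond directions.

    One bead per residue; every bond has length exactly ``bond_length``.
    Requires the ideal-chain settings (no excluded volume, no pair well).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if spec.excluded_radius != 0 or spec.pair_well != 0:
        raise ValueError("generate_fjc requires excluded_radius = 0 and pair_well = 0")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    bonds = _random_unit_vectors(rng, n_frames * (n - 1)).reshape(n_frames, n - 1, 3)
    xyz = np.zeros((n_frames, n, 3))
    xyz[:, 1:, :] = np.cumsum(bonds * spec.bond_length, axis=1)
    top = topology or simple_chain_topology(n)
    return Ensemble(top, xyz)


# ---------------------------------------------------------------------------
# solvent-quality Monte Carlo chain
# ---------------------------------------------------------------------------


class _SquareWellChain:
    """Fixed-bond-length chain with hard core + square-well nonbonded energy.

    Sampled with bond-preserving pivot and crankshaft moves so the ideal
    limit coincides exactly with the freely jointed chain.  Nonbonded pairs
    are those with sequence separation >= 2; energy (in kT) is
    -|pair_well| per pair inside [core, WELL_RANGE_FACTOR * b) when
    ``pair_well`` < 0, +inf inside the core.
    """

    def __init__(self, spec: ChainSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.b = spec.bond_length
        self.core = spec.excluded_radius
        self.eps = -spec.pair_well if spec.pair_well < 0 else 0.0
        self.r_well = WELL_RANGE_FACTOR * self.b
        n = spec.n_residues
        # straight-rod start: no core overlaps for core < 2 b
        self.x = np.zeros((n, 3))
        self.x[:, 0] = np.arange(n) * self.b

    # -- energy bookkeeping --------------------------------------------
    def _pair_energy_against(self, moved: np.ndarray, moved_idx: np.ndarray,
                             fixed: np.ndarray, fixed_idx: np.ndarray) -> float:
        """Nonbonded energy between a moved bead set and a fixed bead set.

        Returns +inf on core overlap.  Bonded (|i-j| < 2) pairs excluded.
        """
        if moved.shape[0] == 0 or fixed.shape[0] == 0:
            return 0.0
        d = cdist(moved, fixed)
        excl = np.abs(moved_idx[:, None] - fixed_idx[None, :]) < 2
        d[excl] = np.inf
        if self.core > 0 and (d < self.core).any():
            return np.inf
        if self.eps == 0.0:
            return 0.0
        inside = (d >= self.core) & (d < self.r_well)
        return -self.eps * float(inside.sum())

    def _attempt_pivot(self) -> None:
        n = self.x.shape[0]
        p = int(self.rng.integers(1, n - 1))
        rot = Rotation.random(rng=self.rng).as_matrix()
        tail = self.x[p + 1 :]
        new_tail = (tail - self.x[p]) @ rot.T + self.x[p]
        idx_tail = np.arange(p + 1, n)
        idx_head = np.arange(0, p + 1)
        head = self.x[: p + 1]
        e_old = self._pair_energy_against(tail, idx_tail, head, idx_head)
        e_new = self._pair_energy_against(new_tail, idx_tail, head, idx_head)
        if self._accept(e_new - e_old):
            self.x[p + 1 :] = new_tail

    def _attempt_crankshaft(self) -> None:
        n = self.x.shape[0]
        i = int(self.rng.integers(0, n))
        others = np.delete(np.arange(n), i)
        if i == 0 or i == n - 1:
            # terminal bead: resample the terminal bond direction
            anchor = self.x[1] if i == 0 else self.x[n - 2]
            new_pos = anchor + self.b * _random_unit_vectors(self.rng, 1)[0]
        else:
            # rotate bead i about the axis through its neighbours
            a, c = self.x[i - 1], self.x[i + 1]
            axis = c - a
            norm = np.linalg.norm(axis)
            if norm < 1e-12:
                return  # neighbours coincide; rotation undefined
            axis = axis / norm
            angle = self.rng.uniform(0, 2 * np.pi)
            rot = Rotation.from_rotvec(axis * angle).as_matrix()
            new_pos = (self.x[i] - a) @ rot.T + a
        idx_i = np.array([i])
        e_old = self._pair_energy_against(self.x[i][None, :], idx_i, self.x[others], others)
        e_new = self._pair_energy_against(new_pos[None, :], idx_i, self.x[others], others)
        if self._accept(e_new - e_old):
            self.x[i] = new_pos

    def _accept(self, delta_e: float) -> bool:
        if delta_e <= 0:
            return True
        if not np.isfinite(delta_e):
            return False
        return self.rng.random() < np.exp(-delta_e)

    def sweep(self) -> None:
        n = self.x.shape[0]
        for _ in range(n):
            if self.rng.random() < 0.3:
                self._attempt_pivot()
            else:
                self._attempt_crankshaft()


def generate_solvent_chain(
    spec: ChainSpec,
    n_frames: int,
    topology: BeadTopology | None = None,
    equilibration_sweeps: int | None = None,
) -> Ensemble:
    """Metropolis Monte Carlo ensemble of a solvent-quality-tunable chain.

    Saves a frame every ``spec.sweeps`` sweeps after an equilibration of
    ``equilibration_sweeps`` (default ``20 * spec.sweeps``).  Frames are
    centred at the chain centroid.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if spec.sweeps < 1:
        raise ValueError("sweeps per saved frame must be >= 1")
    if spec.n_residues < 10:
        raise ValueError("generate_solvent_chain needs n_residues >= 10")
    rng = np.random.default_rng(spec.seed)
    chain = _SquareWellChain(spec, rng)
    burn = 20 * spec.sweeps if equilibration_sweeps is None else equilibration_sweeps
    for _ in range(burn):
        chain.sweep()
    xyz = np.empty((n_frames, spec.n_residues, 3))
    for k in range(n_frames):
        for _ in range(spec.sweeps):
            chain.sweep()
        xyz[k] = chain.x - chain.x.mean(axis=0)
    top = topology or simple_chain_topology(spec.n_residues)
    return Ensemble(top, xyz)


# ---------------------------------------------------------------------------
# Gaussian-chain end-to-end sampler
# ---------------------------------------------------------------------------


def sample_gaussian_dee(xi: float, n: int, seed: int = 0) -> np.ndarray:
    """Draws from p(d) = 4 d^2 exp[-(d/xi)^2] / (sqrt(pi) xi^3).

    Exact sampling: the density is that of the norm of a 3-vector of
    independent zero-mean Gaussians with standard deviation xi / sqrt(2).
    """
    if not xi > 0:
        raise ValueError("xi must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.normal(scale=xi / np.sqrt(2.0), size=(n, 3))
    return np.linalg.norm(v, axis=1)


# ---------------------------------------------------------------------------
# two-domain architecture
# ---------------------------------------------------------------------------


def make_domain_template(
    n_residues: int = 138, radius: float = 1.8, min_separation: float = 0.45, seed: int = 0
) -> np.ndarray:
    """Synthetic rigid-domain template: beads packed uniformly in a sphere.

    A stand-in for a folded-domain structure (one bead per residue) when no
    reference coordinates are supplied: positions are drawn uniformly in a
    sphere of ``radius`` nm with a minimum pairwise separation, giving a
    compact globule of realistic density for a coarse-grained protein domain.
    """
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_residues:
        cand = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(cand) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_separation:
            attempts += 1
            if attempts > 200_000:
                raise PackingError("could not pack domain template; lower the density")
            continue
        pts.append(cand)
    x = np.array(pts)
    return x - x.mean(axis=0)


def generate_two_domain(
    tail_residues: int,
    domain_template: np.ndarray,
    spec: ChainSpec,
    n_frames: int,
    strands: dict[str, tuple[int, int]] | None = None,
    tether_index: int = 0,
    n_molecules: int = 1,
) -> Ensemble:
    """Rigid domain tethered to a flexible tail (disordered-tail architecture).

    The tail (residues ``1..tail_residues``) is sampled by the same Monte
    Carlo sampler as :func:`generate_solvent_chain` with ``spec`` (same seed
    → identical tail coordinates).  Per frame, the domain template is rotated
    rigidly at random and translated so its tether bead (``tether_index``,
    0-based within the domain) sits one bond length beyond the tail's last
    bead.  Tail residues are labelled ``NTD``, domain residues ``CRD``.

    Tail–domain excluded volume is not enforced: the two parts are
    statistically independent by construction.
    """
    template = np.asarray(domain_template, dtype=float)
    if template.ndim != 2 or template.shape[1] != 3:
        raise ValueError("domain_template must be an (n_domain, 3) coordinate array")
    n_dom = template.shape[0]
    if not 0 <= tether_index < n_dom:
        raise ValueError(f"tether bead {tether_index} missing from a {n_dom}-bead domain")
    tail_spec = ChainSpec(
        n_residues=tail_residues,
        bond_length=spec.bond_length,
        excluded_radius=spec.excluded_radius,
        pair_well=spec.pair_well,
        sweeps=spec.sweeps,
        seed=spec.seed,
    )
    tail = generate_solvent_chain(tail_spec, n_frames)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7D0]))
    top = two_domain_topology(
        tail_residues, n_dom, strands=strands, n_molecules=n_molecules
    )
    n_beads = tail_residues + n_dom
    xyz = np.empty((n_frames, n_beads, 3))
    template_centered = template - template[tether_index]
    for k in range(n_frames):
        tail_x = tail.xyz[k]
        xyz[k, :tail_residues] = tail_x
        rot = Rotation.random(rng=rng).as_matrix()
        placed = template_centered @ rot.T
        anchor = tail_x[-1] + spec.bond_length * _random_unit_vectors(rng, 1)[0]
        xyz[k, tail_residues:] = placed + anchor
    if n_molecules > 1:
        # identical copies per frame; generate_box is the intended consumer
        xyz = np.tile(xyz, (1, n_molecules, 1))
    return Ensemble(top, xyz)


# ---------------------------------------------------------------------------
# periodic boxes of several molecules
# ---------------------------------------------------------------------------


def generate_box(
    molecule_ensemble: Ensemble,
    box: BoxSpec,
    n_frames: int,
    molecule: int = 0,
) -> Ensemble:
    """Pack random conformations of one molecule into a periodic cubic box.

    Per frame, ``box.n_molecules`` conformations are drawn (with
    replacement) from ``molecule_ensemble``, rotated randomly, and placed at
    uniform random centers; a placement is rejected when any inter-molecular
    bead distance (minimum image) falls below ``box.tolerance``.  Molecule
    centroids are wrapped into [0, L).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(box.seed)
    src = molecule_ensemble.molecule_xyz(molecule)
    extent = np.max(np.linalg.norm(src - src.mean(axis=1, keepdims=True), axis=2))
    if 2 * extent >= box.box_edge * np.sqrt(3):
        raise PackingError("molecule extent exceeds the box diagonal")
    mol_top = molecule_ensemble.topology.molecules[molecule]
    top = BeadTopology(
        molecules=[mol_top] * box.n_molecules,
        domains=dict(molecule_ensemble.topology.domains),
        strands=dict(molecule_ensemble.topology.strands),
    )
    L = box.box_edge
    n_beads = mol_top.n_beads
    xyz = np.empty((n_frames, box.n_molecules * n_beads, 3))
    for k in range(n_frames):
        placed: list[np.ndarray] = []
        for _ in range(box.n_molecules):
            ok = False
            for _attempt in range(box.max_attempts):
                conf = src[rng.integers(0, src.shape[0])]
                conf = conf - conf.mean(axis=0)
                rot = Rotation.random(rng=rng).as_matrix()
                center = rng.uniform(0.0, L, size=3)
                cand = conf @ rot.T + center
                if all(
                    np.linalg.norm(
                        minimum_image_diffs(cand, other, L), axis=2
                    ).min()
                    >= box.tolerance
                    for other in placed
                ):
                    placed.append(cand)
                    ok = True
                    break
            if not ok:
                raise PackingError(
                    f"frame {k}: failed to place molecule after {box.max_attempts} attempts"
                )
        xyz[k] = np.concatenate(placed, axis=0)
    return Ensemble(top, xyz, box_edge=L)


# ---------------------------------------------------------------------------
# reference scattering curves
# ---------------------------------------------------------------------------


def generate_reference_saxs(
    profile: ScatteringProfile,
    a: float = 1.0,
    b_offset: float = 0.0,
    noise_level: float = 0.02,
    seed: int = 0,
) -> ScatteringProfile:
    """Noisy affine transform of a model curve, as a synthetic reference.

    Returns a * I(q) + b_offset plus Gaussian noise with standard deviation
    ``noise_level * |a * I(q)|``; the profile's sigma column is set to that
    standard deviation, so a chi-square against the generating model is ~1.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    base = a * profile.intensity
    sigma = noise_level * np.abs(base)
    noisy = base + b_offset + rng.normal(size=base.shape) * sigma
    return ScatteringProfile(q=profile.q.copy(), intensity=noisy, sigma=sigma)
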