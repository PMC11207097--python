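"""Bead-level topology for coarse-grained protein models.

A molecule is an ordered list of residues; each residue owns one or more named
beads (Martini-style ``BB``, ``SC1`` ... ``SC5``), exactly one of which is the
backbone bead.  Residue indices are 1-based and all residue intervals
(domains, β-strands) are inclusive, matching the usual sequence numbering of
galectin-3 (residues 1–250, NTD = 1–112, CRD = 113–250).

The topology also carries the domain and β-strand annotation tables used by
the contact-statistics module.  The galectin-3 tables ship as module-level
constants (:data:`GALECTIN3_DOMAINS`, :data:`GALECTIN3_STRANDS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError

#: Residue names carrying an aromatic side chain (the flag the contact
#: analyses highlight).
AROMATIC_RESIDUES = frozenset({"PHE", "TRP", "TYR"})

#: Galectin-3 domain boundaries: the disordered N-terminal domain and the
#: folded carbohydrate recognition domain (1-based, inclusive).
GALECTIN3_DOMAINS: dict[str, tuple[int, int]] = {
    "NTD": (1, 112),
    "CRD": (113, 250),
}

#: β-strand residue intervals of the galectin-3 CRD (1-based, inclusive).
GALECTIN3_STRANDS: dict[str, tuple[int, int]] = {
    "beta1": (118, 121),
    "beta2": (130, 138),
    "beta3": (145, 151),
    "beta4": (154, 162),
    "beta5": (170, 174),
    "beta6": (185, 187),
    "beta7": (197, 204),
    "beta8": (208, 213),
    "beta9": (216, 222),
    "beta10": (233, 238),
    "beta11": (240, 249),
}


@dataclass(frozen=True)
class Residue:
    """One residue: 1-based sequence index, 3-letter name, named beads.

    ``backbone`` is the position of the backbone bead within ``beads``.
    """

    index: int
    name: str
    beads: tuple[str, ...] = ("BB",)
    backbone: int = 0

    def __post_init__(self) -> None:
        if len(self.beads) < 1:
            raise TopologyError(f"residue {self.index}: needs at least one bead")
        if not 0 <= self.backbone < len(self.beads):
            raise TopologyError(
                f"residue {self.index}: backbone bead position {self.backbone} "
                f"out of range for {len(self.beads)} beads"
            )

    @property
    def aromatic(self) -> bool:
        return self.name.upper() in AROMATIC_RESIDUES

    @property
    def n_beads(self) -> int:
        return len(self.beads)


class MoleculeTopology:
    """Ordered residues of one molecule plus cached bead-index arrays."""

    def __init__(self, residues: list[Residue]):
        if not residues:
            raise TopologyError("molecule must have at least one residue")
        expected = list(range(1, len(residues) + 1))
        if [r.index for r in residues] != expected:
            raise TopologyError("residue indices must run 1..n_residues in order")
        self.residues = list(residues)
        counts = np.array([r.n_beads for r in residues])
        # bead layout: beads of residue k are contiguous, residues in order
        self.bead_offsets = np.concatenate([[0], np.cumsum(counts)])
        self.n_beads = int(self.bead_offsets[-1])
        self.bead_residue = np.repeat(np.arange(len(residues)), counts)
        self.backbone_beads = np.array(
            [self.bead_offsets[k] + r.backbone for k, r in enumerate(residues)]
        )

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_bead_slice(self, residue_index: int) -> slice:
        """Beads of 1-based residue ``residue_index`` within the molecule."""
        k = residue_index - 1
        return slice(int(self.bead_offsets[k]), int(self.bead_offsets[k + 1]))

    @property
    def aromatic_mask(self) -> np.ndarray:
        return np.array([r.aromatic for r in self.residues])


@dataclass
class BeadTopology:
    """Topology of a (possibly multi-molecule) system.

    Molecules are positional: frame coordinates concatenate the molecules in
    this fixed order.  Domain and strand intervals are 1-based inclusive and
    apply to every molecule (the systems modelled here contain identical
    copies of one protein).
    """

    molecules: list[MoleculeTopology]
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    strands: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.molecules:
            raise TopologyError("topology needs at least one molecule")
        self.validate()

    # -- derived layout -------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_beads_total(self) -> int:
        return sum(m.n_beads for m in self.molecules)

    def molecule_bead_slice(self, molecule: int) -> slice:
        if not 0 <= molecule < self.n_molecules:
            raise TopologyError(f"no molecule {molecule} (have {self.n_molecules})")
        start = sum(m.n_beads for m in self.molecules[:molecule])
        return slice(start, start + self.molecules[molecule].n_beads)

    # -- annotation helpers ---------------------------------------------
    def domain_residues(self, domain: str) -> np.ndarray:
        """1-based residue indices of a named domain."""
        try:
            lo, hi = self.domains[domain]
        except KeyError:
            raise TopologyError(f"no domain named {domain!r}") from None
        return np.arange(lo, hi + 1)

    def strand_residues(self, strand: str) -> np.ndarray:
        try:
            lo, hi = self.strands[strand]
        except KeyError:
            raise TopologyError(f"no strand named {strand!r}") from None
        return np.arange(lo, hi + 1)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n_res = self.molecules[0].n_residues
        if self.domains:
            covered = np.zeros(n_res, dtype=int)
            for name, (lo, hi) in self.domains.items():
                if not (1 <= lo <= hi <= n_res):
                    raise TopologyError(
                        f"domain {name!r} interval ({lo}, {hi}) outside 1..{n_res}"
                    )
                covered[lo - 1 : hi] += 1
            if (covered > 1).any():
                raise TopologyError("domain ranges overlap")
            if (covered == 0).any():
                raise TopologyError("domain ranges do not cover 1..n_residues")
        for name, (lo, hi) in self.strands.items():
            if not (1 <= lo <= hi <= n_res):
                raise TopologyError(
                    f"strand {name!r} interval ({lo}, {hi}) outside 1..{n_res}"
                )
            if self.domains:
                inside = any(
                    dlo <= lo and hi <= dhi for dlo, dhi in self.domains.values()
                )
                if not inside:
                    raise TopologyError(f"strand {name!r} crosses a domain boundary")


def simple_chain_topology(
    n_residues: int,
    n_molecules: int = 1,
    residue_names: list[str] | None = None,
    domains: dict[str, tuple[int, int]] | None = None,
    strands: dict[str, tuple[int, int]] | None = None,
) -> BeadTopology:
    """One-bead-per-residue chain topology (the generator default).

    If ``domains`` is omitted a single domain ``"chain"`` covering every
    residue is used, so domain-aware operations stay well defined.
    """
    if n_residues < 1:
        raise TopologyError("n_residues must be >= 1")
    if residue_names is None:
        residue_names = ["GLY"] * n_residues
    if len(residue_names) != n_residues:
        raise TopologyError("residue_names length must equal n_residues")
    residues = [Residue(i + 1, residue_names[i]) for i in range(n_residues)]
    mol = MoleculeTopology(residues)
    if domains is None:
        domains = {"chain": (1, n_residues)}
    return BeadTopology(
        molecules=[MoleculeTopology(residues) for _ in range(n_molecules)]
        if n_molecules > 1
        else [mol],
        domains=domains,
        strands=strands or {},
    )


def two_domain_topology(
    tail_residues: int,
    domain_residues: int,
    tail_names: list[str] | None = None,
    strands: dict[str, tuple[int, int]] | None = None,
    tail_label: str = "NTD",
    domain_label: str = "CRD",
    n_molecules: int = 1,
) -> BeadTopology:
    """Topology of a flexible tail tethered to a folded domain.

    Mirrors the galectin-3 architecture: a disordered N-terminal tail
    (residues ``1..tail_residues``) followed by a rigid domain.  ``strands``
    intervals are given in absolute residue numbering (inside the domain
    range), e.g. the galectin-3 β-strand table for a 112+138 system.
    """
    n_res = tail_residues + domain_residues
    names = (tail_names or ["GLY"] * tail_residues) + ["ALA"] * domain_residues
    if len(names) != n_res:
        raise TopologyError("tail_names length must equal tail_residues")
    residues = [Residue(i + 1, names[i]) for i in range(n_res)]
    domains = {
        tail_label: (1, tail_residues),
        domain_label: (tail_residues + 1, n_res),
    }
    mols = [MoleculeTopology(residues) for _ in range(n_molecules)]
    return BeadTopology(molecules=mols, domains=domains, strands=strands or {})


def galectin3_like_topology(
    n_molecules: int = 1, aromatic_positions: tuple[int, ...] = ()
) -> BeadTopology:
    """250-residue, one-bead-per-residue topology with the galectin-3 tables.

    ``aromatic_positions`` lets a synthetic sequence mark chosen 1-based
    residues as PHE so that aromatic-residue analyses have something to see.
    """
    names = ["GLY"] * 250
    for pos in aromatic_positions:
        names[pos - 1] = "PHE"
    return simple_chain_topology(
        250,
        n_molecules=n_molecules,
        residue_names=names,
        domains=dict(GALECTIN3_DOMAINS),
        strands=dict(GALECTIN3_STRANDS),
    )
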