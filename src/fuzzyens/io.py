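"""Readers and writers for ensembles, topology configs and SAXS curves.

Coordinate formats
------------------
* Multi-model PDB (``MODEL``/``ENDMDL`` records), read and written through
  mdtraj.  On disk PDB is in ångström; in memory everything is nm.
* XYZ trajectories through :class:`mdtraj.formats.XYZTrajectoryFile`.  The
  XYZ format carries no unit convention; this package defines on-disk XYZ
  coordinates to be in nm, so values pass through unchanged.

Topology configs are JSON; SAXS curves are 3-column whitespace text
(q [nm^-1], I [a.u.], sigma), ``#`` comments allowed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import mdtraj as md
import numpy as np
from mdtraj.core import element as md_element
from mdtraj.formats import XYZTrajectoryFile

from .ensemble import Ensemble
from .errors import FormatError, TopologyError
from .saxs import ScatteringProfile
from .topology import BeadTopology, MoleculeTopology, Residue

# ---------------------------------------------------------------------------
# topology JSON
# ---------------------------------------------------------------------------


def _molecule_to_dict(mol: MoleculeTopology) -> dict:
    return {
        "residues": [
            {
                "index": r.index,
                "name": r.name,
                "beads": list(r.beads),
                "backbone": r.backbone,
            }
            for r in mol.residues
        ]
    }


def _molecule_from_dict(d: dict) -> MoleculeTopology:
    residues = [
        Residue(
            index=int(r["index"]),
            name=str(r["name"]),
            beads=tuple(r.get("beads", ["BB"])),
            backbone=int(r.get("backbone", 0)),
        )
        for r in d["residues"]
    ]
    return MoleculeTopology(residues)


def write_topology(topology: BeadTopology, path: str | Path) -> None:
    """Serialise a :class:`BeadTopology` to a JSON config."""
    mols = [_molecule_to_dict(m) for m in topology.molecules]
    # identical molecules are stored once with a replication count
    if len(mols) > 1 and all(m == mols[0] for m in mols[1:]):
        payload: dict = {"molecule": mols[0], "n_molecules": len(mols)}
    else:
        payload = {"molecules": mols}
    payload["domains"] = {k: list(v) for k, v in topology.domains.items()}
    payload["strands"] = {k: list(v) for k, v in topology.strands.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_topology(path: str | Path) -> BeadTopology:
    """Load a JSON topology config."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        if "molecule" in payload:
            n = int(payload.get("n_molecules", 1))
            mols = [_molecule_from_dict(payload["molecule"]) for _ in range(n)]
        else:
            mols = [_molecule_from_dict(m) for m in payload["molecules"]]
        domains = {k: (int(v[0]), int(v[1])) for k, v in payload.get("domains", {}).items()}
        strands = {k: (int(v[0]), int(v[1])) for k, v in payload.get("strands", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed topology config ({exc})") from exc
    return BeadTopology(molecules=mols, domains=domains, strands=strands)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------


def _mdtraj_topology(topology: BeadTopology) -> md.Topology:
    top = md.Topology()
    for mol in topology.molecules:
        chain = top.add_chain()
        for res in mol.residues:
            r = top.add_residue(res.name, chain, resSeq=res.index)
            for bead in res.beads:
                top.add_atom(bead, md_element.virtual_site, r)
    return top


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as multi-model PDB (``.pdb``) or XYZ (``.xyz``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        traj = md.Trajectory(
            ensemble.xyz.astype(np.float32), _mdtraj_topology(ensemble.topology)
        )
        if ensemble.box_edges is not None:
            L = ensemble.box_edges
            traj.unitcell_lengths = np.column_stack([L, L, L]).astype(np.float32)
            traj.unitcell_angles = np.full((len(L), 3), 90.0, dtype=np.float32)
        traj.save_pdb(str(path))
    elif suffix == ".xyz":
        with XYZTrajectoryFile(str(path), "w") as fh:
            fh.write(ensemble.xyz)  # on-disk XYZ defined as nm
    else:
        raise FormatError(f"unsupported coordinate format: {path.name!r}")


def read_ensemble(
    coordinate_path: str | Path,
    topology_path: str | Path | None = None,
    topology: BeadTopology | None = None,
    box_edge: float | None = None,
) -> Ensemble:
    """Read a multi-model PDB or XYZ trajectory against a topology.

    Exactly one of ``topology_path`` (JSON config) or ``topology`` must be
    given.  PDB coordinates are converted Å → nm by mdtraj; XYZ is read as
    nm.  ``box_edge`` overrides/provides the cubic box edge for formats that
    do not carry one (XYZ, or PDB without a CRYST1 record).
    """
    if (topology is None) == (topology_path is None):
        raise ValueError("provide exactly one of topology_path or topology")
    if topology is None:
        topology = read_topology(topology_path)

    coordinate_path = Path(coordinate_path)
    suffix = coordinate_path.suffix.lower()
    if suffix == ".pdb":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = md.load_pdb(str(coordinate_path))
        except Exception as exc:
            raise FormatError(f"{coordinate_path}: cannot parse PDB ({exc})") from exc
        xyz = np.asarray(traj.xyz, dtype=float)
        edges = None
        if traj.unitcell_lengths is not None:
            edges = np.asarray(traj.unitcell_lengths[:, 0], dtype=float)
    elif suffix == ".xyz":
        try:
            with XYZTrajectoryFile(str(coordinate_path)) as fh:
                xyz = np.asarray(fh.read(), dtype=float)
        except Exception as exc:
            raise FormatError(f"{coordinate_path}: cannot parse XYZ ({exc})") from exc
        if xyz.size == 0:
            raise FormatError(f"{coordinate_path}: empty trajectory")
        edges = None
    else:
        raise FormatError(f"unsupported coordinate format: {coordinate_path.name!r}")

    if xyz.shape[1] != topology.n_beads_total:
        raise TopologyError(
            f"{coordinate_path}: frame 0 has {xyz.shape[1]} beads, topology "
            f"expects {topology.n_beads_total}"
        )
    if box_edge is not None:
        edges = box_edge
    return Ensemble(topology, xyz, box_edge=edges)


# ---------------------------------------------------------------------------
# SAXS curves
# ---------------------------------------------------------------------------


def read_saxs_curve(path: str | Path) -> ScatteringProfile:
    """Read a 3-column (q, I, sigma) whitespace text file.

    q must be strictly increasing and sigma strictly positive; the third
    column may be omitted for model curves without error estimates.
    """
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise FormatError(f"{path}: inconsistent column counts {sorted(ncols)}")
    arr = np.array(rows, dtype=float)
    q, intensity = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    if not (np.diff(q) > 0).all():
        raise FormatError(f"{path}: q values must be strictly increasing")
    if sigma is not None and not (sigma > 0).all():
        raise FormatError(f"{path}: sigma values must be positive")
    return ScatteringProfile(q=q, intensity=intensity, sigma=sigma)


def write_saxs_curve(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a profile as 3-column (or 2-column, if no sigma) text."""
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    header = "q[1/nm] I[a.u.]" + (" sigma" if profile.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.10g")
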