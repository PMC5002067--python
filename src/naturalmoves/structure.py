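"""Conformations, trajectories and PDB input/output.

Two in-memory representations are used throughout the package:

* ``cg3`` -- a three-site-per-residue coarse-grained protein model
  (backbone N, CA and a sidechain centroid site ``SC``), connected by
  pseudo-bonds N-CA, CA-SC and CA(i)-CA(i+1);
* ``all-atom-dna`` -- an idealized all-heavy-atom DNA duplex with a
  simplified sugar/backbone (P, O5', C5', C4', C3', O3', C1') and planar
  base templates.

PDB reading and writing goes through biotite; bond topology and the ideal
bond lengths used by geometry validation are carried on the
:class:`Conformation` itself (PDB files do not store them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Conformation",
    "Trajectory",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "coarse_grain_protein",
]


class PDBParseError(ValueError):
    pass


@dataclass
class Conformation:
    """Atom coordinates plus topology for a protein or DNA model.

    ``bonds`` holds atom-index pairs and ``bond_r0`` the ideal length of each
    bond; for synthetic fixtures the ideal lengths are the as-built ones, so a
    freshly constructed conformation always passes geometry validation.
    """

    atom_name: np.ndarray  # (N,) str
    res_id: np.ndarray  # (N,) int
    chain_id: np.ndarray  # (N,) str
    res_name: np.ndarray  # (N,) str
    element: np.ndarray  # (N,) str
    coords: np.ndarray  # (N,3) float64, Angstrom
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    model_kind: str = "unknown"  # "cg3" | "all-atom-dna" | "all-atom-protein" | ...

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self._index: dict[tuple[str, int, str], int] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def copy(self) -> "Conformation":
        return Conformation(
            atom_name=self.atom_name.copy(),
            res_id=self.res_id.copy(),
            chain_id=self.chain_id.copy(),
            res_name=self.res_name.copy(),
            element=self.element.copy(),
            coords=self.coords.copy(),
            bonds=self.bonds.copy(),
            bond_r0=self.bond_r0.copy(),
            model_kind=self.model_kind,
        )

    # -- lookup helpers -------------------------------------------------

    def _build_index(self) -> dict[tuple[str, int, str], int]:
        if self._index is None:
            self._index = {
                (c, int(r), a): i
                for i, (c, r, a) in enumerate(
                    zip(self.chain_id, self.res_id, self.atom_name)
                )
            }
        return self._index

    def atom_index(self, chain: str, res: int, atom: str) -> int:
        try:
            return self._build_index()[(chain, int(res), atom)]
        except KeyError:
            raise KeyError(f"no atom {chain}:{res}:{atom}") from None

    def has_atom(self, chain: str, res: int, atom: str) -> bool:
        return (chain, int(res), atom) in self._build_index()

    def residue_atoms(self, chain: str, res: int) -> np.ndarray:
        return np.where((self.chain_id == chain) & (self.res_id == int(res)))[0]

    def chain_residues(self, chain: str) -> np.ndarray:
        return np.unique(self.res_id[self.chain_id == chain])

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.atom_name = self.atom_name
        arr.res_id = self.res_id
        arr.chain_id = self.chain_id
        arr.res_name = self.res_name
        arr.element = self.element
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        return arr


@dataclass
class Trajectory:
    """Sampled conformations sharing one topology, with per-frame energies."""

    topology: Conformation
    frames: list[np.ndarray]
    energies: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Conformation:
        conf = self.topology.copy()
        conf.coords = np.array(self.frames[i], dtype=float)
        return conf

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


def _prescan_pdb(path: Path) -> None:
    """Line-level sanity check so malformed ATOM records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}: truncated {rec} record at line {lineno}"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: unparsable coordinates at line {lineno}"
                    ) from None


def read_pdb(path: str | Path, template: Conformation | None = None):
    """Read a PDB file into a :class:`Conformation` (or, for multi-MODEL
    files, a :class:`Trajectory`).

    PDB files carry no bond topology; pass ``template`` (a conformation with
    matching atoms, e.g. the fixture the file was written from) to inherit its
    bonds, ideal bond lengths and model kind.
    """
    path = Path(path)
    _prescan_pdb(path)
    pdbfile = pdb.PDBFile.read(str(path))
    stack = pdbfile.get_structure(model=None)  # AtomArrayStack
    n_models = stack.stack_depth()

    def to_conf(arr: struc.AtomArray) -> Conformation:
        conf = Conformation(
            atom_name=np.asarray(arr.atom_name),
            res_id=np.asarray(arr.res_id, dtype=int),
            chain_id=np.asarray(arr.chain_id),
            res_name=np.asarray(arr.res_name),
            element=np.asarray(arr.element),
            coords=np.asarray(arr.coord, dtype=float),
        )
        if template is not None:
            if template.n_atoms != conf.n_atoms:
                raise ValueError(
                    f"template has {template.n_atoms} atoms, file has {conf.n_atoms}"
                )
            conf.bonds = template.bonds.copy()
            conf.bond_r0 = template.bond_r0.copy()
            conf.model_kind = template.model_kind
        return conf

    if n_models == 1:
        return to_conf(stack[0])
    first = to_conf(stack[0])
    frames = [np.asarray(stack[i].coord, dtype=float) for i in range(n_models)]
    return Trajectory(topology=first, frames=frames)


def write_pdb(obj: Conformation | Trajectory, path: str | Path) -> None:
    """Write a conformation (single MODEL) or trajectory (multi-MODEL) PDB."""
    if isinstance(obj, Trajectory):
        arrs = []
        for coords in obj.frames:
            arr = obj.topology.to_atom_array()
            arr.coord = np.asarray(coords, dtype=np.float32)
            arrs.append(arr)
        stack = struc.stack(arrs)
        pdbfile = pdb.PDBFile()
        pdbfile.set_structure(stack)
    else:
        pdbfile = pdb.PDBFile()
        pdbfile.set_structure(obj.to_atom_array())
    pdbfile.write(str(path))


_BACKBONE = ("N", "CA", "C")


def coarse_grain_protein(conf: Conformation) -> Conformation:
    """Map an all-atom protein to the three-site-per-residue (cg3) model.

    Sites per residue: backbone N, backbone CA, and ``SC`` at the centroid of
    the sidechain heavy atoms (CB if only CB is present; glycine, having no
    sidechain, gets an SC site coincident with CA).  Pseudo-bonds: N-CA and
    CA-SC within a residue, CA-CA between consecutive residues of a chain.
    Ideal bond lengths are taken from the mapped geometry.
    """
    names, resids, chains, resnames, elements, coords = [], [], [], [], [], []
    backbone_set = {"N", "CA", "C", "O", "OXT"}
    for chain in dict.fromkeys(conf.chain_id):
        for res in conf.chain_residues(chain):
            idx = conf.residue_atoms(chain, res)
            atom_names = conf.atom_name[idx]
            for bb in ("N", "CA"):
                if bb not in atom_names:
                    raise ValueError(
                        f"residue {chain}:{res} missing backbone atom {bb}"
                    )
            if "C" not in atom_names:
                raise ValueError(f"residue {chain}:{res} missing backbone atom C")
            n_xyz = conf.coords[conf.atom_index(chain, res, "N")]
            ca_xyz = conf.coords[conf.atom_index(chain, res, "CA")]
            side = idx[[a not in backbone_set for a in atom_names]]
            sc_xyz = conf.coords[side].mean(axis=0) if len(side) else ca_xyz.copy()
            resname = conf.res_name[idx[0]]
            for name, xyz, elem in (("N", n_xyz, "N"), ("CA", ca_xyz, "C"), ("SC", sc_xyz, "C")):
                names.append(name)
                resids.append(int(res))
                chains.append(chain)
                resnames.append(resname)
                elements.append(elem)
                coords.append(xyz)

    cg = Conformation(
        atom_name=np.array(names),
        res_id=np.array(resids, dtype=int),
        chain_id=np.array(chains),
        res_name=np.array(resnames),
        element=np.array(elements),
        coords=np.array(coords, dtype=float),
        model_kind="cg3",
    )
    cg.bonds, cg.bond_r0 = cg3_bonds(cg)
    return cg


def cg3_bonds(cg: Conformation) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-bond topology for a cg3 conformation; ideal lengths are the
    current geometry's."""
    bonds = []
    for chain in dict.fromkeys(cg.chain_id):
        residues = cg.chain_residues(chain)
        for res in residues:
            bonds.append((cg.atom_index(chain, res, "N"), cg.atom_index(chain, res, "CA")))
            bonds.append((cg.atom_index(chain, res, "CA"), cg.atom_index(chain, res, "SC")))
        for r0, r1 in zip(residues, residues[1:]):
            if r1 == r0 + 1:
                bonds.append((cg.atom_index(chain, r0, "CA"), cg.atom_index(chain, r1, "CA")))
    arr = np.array(bonds, dtype=int)
    r0 = np.linalg.norm(cg.coords[arr[:, 0]] - cg.coords[arr[:, 1]], axis=1)
    return arr, r0
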