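"""Simplified, swappable potential energy models.

The sampling protocol is agnostic to the force field; these potentials are
deliberately minimal -- just enough structure (bonded wells, excluded volume,
native contacts / Watson-Crick wells) to give the Metropolis walk a
meaningful landscape on the synthetic fixtures.  Units are kcal/mol and
Angstrom throughout; ``KB`` is Boltzmann's constant in kcal/(mol K) so
temperatures are in Kelvin.

A model is a list of terms.  Every term can evaluate its total energy and an
incremental difference given the set of moved atoms, and the incremental
path is contract-tested against full recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .structure import Conformation

__all__ = [
    "KB",
    "EnergyModel",
    "HarmonicBonds",
    "SoftRepulsion",
    "NativeContacts",
    "HarmonicTether",
    "CustomTerm",
    "total_energy",
    "delta_energy",
    "protein_energy_model",
    "dna_energy_model",
]

KB = 0.0019872041  # kcal/(mol K)


def _pair_energy_harmonic(coords: np.ndarray, pairs: np.ndarray, r0: np.ndarray, k) -> float:
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(np.sum(k * (d - r0) ** 2))


@dataclass
class HarmonicBonds:
    """k (r - r0)^2 over an explicit bond list."""

    pairs: np.ndarray
    r0: np.ndarray
    k: float = 20.0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def energy(self, coords: np.ndarray) -> float:
        return _pair_energy_harmonic(coords, self.pairs, self.r0, self.k)

    def delta(self, new: np.ndarray, old: np.ndarray, moved: np.ndarray) -> float:
        if len(self.pairs) == 0:
            return 0.0
        sel = moved[self.pairs[:, 0]] | moved[self.pairs[:, 1]]
        p, r = self.pairs[sel], self.r0[sel]
        return _pair_energy_harmonic(new, p, r, self.k) - _pair_energy_harmonic(old, p, r, self.k)


@dataclass
class NativeContacts:
    """Go-style harmonic wells about native pair distances."""

    pairs: np.ndarray
    r0: np.ndarray
    k: float = 0.2

    __post_init__ = HarmonicBonds.__post_init__
    energy = HarmonicBonds.energy
    delta = HarmonicBonds.delta


@dataclass
class SoftRepulsion:
    """Purely repulsive excluded volume over a fixed candidate pair list.

    E = eps ((sigma/r)^12 - 1) for r < sigma, 0 beyond -- continuous at the
    cutoff, so the fixed pair list is an exact description of the potential.
    """

    pairs: np.ndarray
    eps: float = 1.0
    sigma: float = 4.0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.eps < 0 or self.sigma <= 0:
            raise ValueError("eps must be >= 0 and sigma > 0")

    def _e(self, coords: np.ndarray, pairs: np.ndarray) -> float:
        if len(pairs) == 0:
            return 0.0
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        d = np.maximum(d, 1e-6)
        inside = d < self.sigma
        if not inside.any():
            return 0.0
        x = (self.sigma / d[inside]) ** 12 - 1.0
        return float(self.eps * np.sum(x))

    def energy(self, coords: np.ndarray) -> float:
        return self._e(coords, self.pairs)

    def delta(self, new: np.ndarray, old: np.ndarray, moved: np.ndarray) -> float:
        if len(self.pairs) == 0:
            return 0.0
        sel = moved[self.pairs[:, 0]] | moved[self.pairs[:, 1]]
        p = self.pairs[sel]
        return self._e(new, p) - self._e(old, p)


@dataclass
class HarmonicTether:
    """(k/2) |r - center|^2 restraints on individual atoms.

    Breaks rigid-motion invariance by design; used for analytically solvable
    test systems, not in the default models.
    """

    atoms: np.ndarray
    centers: np.ndarray
    k: float = 1.0

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=int).reshape(-1)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def _e(self, coords: np.ndarray, sel: np.ndarray) -> float:
        d2 = np.sum((coords[self.atoms[sel]] - self.centers[sel]) ** 2, axis=1)
        return float(0.5 * self.k * np.sum(d2))

    def energy(self, coords: np.ndarray) -> float:
        return self._e(coords, np.ones(len(self.atoms), dtype=bool))

    def delta(self, new: np.ndarray, old: np.ndarray, moved: np.ndarray) -> float:
        sel = moved[self.atoms]
        return self._e(new, sel) - self._e(old, sel)


@dataclass
class CustomTerm:
    """Arbitrary function of the coordinates of a fixed atom set."""

    atoms: np.ndarray
    fn: Callable[[np.ndarray], float]

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=int).reshape(-1)

    def energy(self, coords: np.ndarray) -> float:
        return float(self.fn(coords[self.atoms]))

    def delta(self, new: np.ndarray, old: np.ndarray, moved: np.ndarray) -> float:
        if not moved[self.atoms].any():
            return 0.0
        return self.energy(new) - self.energy(old)


@dataclass
class EnergyModel:
    terms: list
    kind: str = "generic"  # matching Conformation.model_kind, or "generic"


def total_energy(conf: Conformation | np.ndarray, model: EnergyModel) -> float:
    """Sum of all term energies (kcal/mol); deterministic, and invariant
    under global rigid-body motion for models without positional restraints."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, dtype=float)
    if model.kind != "generic" and isinstance(conf, Conformation) and conf.model_kind != model.kind:
        raise ValueError(f"model kind {model.kind!r} does not match conformation {conf.model_kind!r}")
    return float(sum(t.energy(coords) for t in model.terms))


def delta_energy(
    new_coords: np.ndarray,
    old_coords: np.ndarray,
    moved_atoms: Sequence[int] | np.ndarray,
    model: EnergyModel,
) -> float:
    """E(new) - E(old), evaluating only terms that touch ``moved_atoms``.

    Matches full recomputation to 1e-9 provided atoms outside ``moved_atoms``
    are identical in both coordinate sets.
    """
    moved_atoms = np.asarray(moved_atoms, dtype=int)
    if moved_atoms.size == 0:
        return 0.0
    moved = np.zeros(len(new_coords), dtype=bool)
    moved[moved_atoms] = True
    return float(sum(t.delta(new_coords, old_coords, moved) for t in model.terms))


# --------------------------------------------------------------------------
# default models for the fixtures
# --------------------------------------------------------------------------


def _candidate_pairs(conf: Conformation, min_res_sep: int = 2) -> np.ndarray:
    """All atom pairs at least ``min_res_sep`` residues apart (or on
    different chains), excluding bonded pairs."""
    n = conf.n_atoms
    i, j = np.triu_indices(n, k=1)
    same_chain = conf.chain_id[i] == conf.chain_id[j]
    res_sep = np.abs(conf.res_id[i] - conf.res_id[j])
    keep = ~same_chain | (res_sep >= min_res_sep)
    bonded = {(int(a), int(b)) for a, b in conf.bonds} | {
        (int(b), int(a)) for a, b in conf.bonds
    }
    pairs = np.column_stack([i[keep], j[keep]])
    if bonded:
        mask = np.array([(int(a), int(b)) not in bonded for a, b in pairs])
        pairs = pairs[mask]
    return pairs


def protein_energy_model(
    conf: Conformation,
    bond_k: float = 20.0,
    rep_eps: float = 1.0,
    rep_sigma: float = 4.0,
    contact_k: float = 0.2,
    contact_cutoff: float = 9.0,
    contacts: bool = True,
) -> EnergyModel:
    """Go-type model for the cg3 protein fixtures: harmonic pseudo-bonds,
    soft-core repulsion, and native-contact wells taken from the input
    geometry (so the built state is the energy minimum, while concerted
    segment motion remains accessible)."""
    if conf.model_kind != "cg3":
        raise ValueError("protein model expects a cg3 conformation")
    terms: list = [HarmonicBonds(conf.bonds, conf.bond_r0, k=bond_k)]
    pairs = _candidate_pairs(conf, min_res_sep=2)
    terms.append(SoftRepulsion(pairs, eps=rep_eps, sigma=rep_sigma))
    if contacts:
        ca = conf.atom_name == "CA"
        cpairs = pairs[ca[pairs[:, 0]] & ca[pairs[:, 1]]]
        d = np.linalg.norm(conf.coords[cpairs[:, 0]] - conf.coords[cpairs[:, 1]], axis=1)
        native = cpairs[d < contact_cutoff]
        terms.append(
            NativeContacts(native, np.linalg.norm(
                conf.coords[native[:, 0]] - conf.coords[native[:, 1]], axis=1
            ), k=contact_k)
        )
    return EnergyModel(terms=terms, kind="cg3")


def dna_energy_model(
    conf: Conformation,
    bond_k: float = 50.0,
    wc_k: float = 5.0,
    stack_k: float = 2.0,
) -> EnergyModel:
    """Minimal duplex model: harmonic bonds on the full covalent topology,
    Watson-Crick distance wells between paired N1/N3 atoms, and
    nearest-neighbour stacking wells on intra-strand C1'-C1' distances.
    Well minima are the as-built distances."""
    if conf.model_kind != "all-atom-dna":
        raise ValueError("dna model expects an all-atom-dna conformation")
    from .fixtures import basepairs  # local import to avoid a cycle

    terms: list = [HarmonicBonds(conf.bonds, conf.bond_r0, k=bond_k)]

    wc = []
    for (ca, ra), (cb, rb) in basepairs(conf):
        rname_a = conf.res_name[conf.residue_atoms(ca, ra)[0]]
        atom_a = "N1" if rname_a in ("DA", "DG") else "N3"
        atom_b = "N3" if atom_a == "N1" else "N1"
        wc.append((conf.atom_index(ca, ra, atom_a), conf.atom_index(cb, rb, atom_b)))
    wc = np.array(wc, dtype=int)
    wc_r0 = np.linalg.norm(conf.coords[wc[:, 0]] - conf.coords[wc[:, 1]], axis=1)
    terms.append(NativeContacts(wc, wc_r0, k=wc_k))

    stack = []
    for chain in dict.fromkeys(conf.chain_id):
        residues = conf.chain_residues(chain)
        for r0_, r1_ in zip(residues, residues[1:]):
            stack.append((conf.atom_index(chain, r0_, "C1'"), conf.atom_index(chain, r1_, "C1'")))
    stack = np.array(stack, dtype=int)
    stack_r0 = np.linalg.norm(conf.coords[stack[:, 0]] - conf.coords[stack[:, 1]], axis=1)
    terms.append(NativeContacts(stack, stack_r0, k=stack_k))
    return EnergyModel(terms=terms, kind="all-atom-dna")
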