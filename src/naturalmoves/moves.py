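"""Natural-move proposal generators induced by an effective decomposition.

Each effective segment gets exactly one rigid-body generator (three
translations + three rotations about the segment centroid) -- so segments
fused by a deactivated molten zone share a single generator and their
relative arrangement is preserved for the whole run.  Each active torsion
gets a generator rotating its moving set about the bond axis.  All proposal
densities are symmetric, as the Metropolis criterion requires.

Atoms of permanently active *terminal* molten zones (free chain ends) ride
rigidly with their only neighbouring segment; interior active zones are
closure regions, and each rigid generator carries the closure problems for
the zones flanking it.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .closure import ClosureProblem
from .decomposition import EffectiveDecomposition, MoltenZone, TorsionDOF
from .structure import Conformation

__all__ = [
    "StepConfig",
    "MoveGenerator",
    "MoveSet",
    "build_moveset",
    "propose_rigid",
    "propose_torsion",
    "propose_bend",
    "rigid_transform",
]


@dataclass
class StepConfig:
    """Maximum step sizes: translation (A), rotation and torsion (degrees)."""

    max_trans: float = 0.5
    max_rot: float = 5.0
    max_torsion: float = 15.0


@dataclass
class MoveGenerator:
    kind: str  # "rigid" | "torsion" | "bend"
    label: str
    atoms: np.ndarray  # atoms displaced by the proposal itself
    max_trans: float = 0.0
    max_rot: float = 0.0  # degrees; torsion/bend amplitude for non-rigid kinds
    weight: float = 1.0
    axis: tuple[int, int] | None = None  # (b, c) atom indices for torsion/bend
    closures: tuple[ClosureProblem, ...] = ()

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=int)
        if self.weight <= 0:
            raise ValueError("generator weight must be > 0")
        if len(self.atoms) < 1:
            raise ValueError(f"generator {self.label!r} moves no atoms")

    def moved_atoms(self) -> np.ndarray:
        """Atoms the move may displace, including closure regions."""
        parts = [self.atoms] + [p.all_moved for p in self.closures]
        return np.unique(np.concatenate(parts))


@dataclass
class MoveSet:
    generators: list[MoveGenerator]

    def __post_init__(self) -> None:
        if not self.generators:
            raise ValueError("empty move set")

    def copy(self) -> "MoveSet":
        return MoveSet(generators=[_copy.deepcopy(g) for g in self.generators])

    @property
    def weights(self) -> np.ndarray:
        return np.array([g.weight for g in self.generators])


# --------------------------------------------------------------------------
# proposal primitives
# --------------------------------------------------------------------------


def rigid_transform(
    coords: np.ndarray,
    atoms: np.ndarray,
    translation: np.ndarray,
    axis: np.ndarray,
    angle_deg: float,
    center: np.ndarray | None = None,
) -> None:
    """Apply rotation (about ``center``, default the atoms' centroid) then
    translation to ``atoms``, in place.  Internal geometry is preserved
    exactly (orthogonal transform)."""
    sub = coords[atoms]
    if center is None:
        center = sub.mean(axis=0)
    if angle_deg != 0.0:
        rot = Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis, dtype=float))
        sub = (sub - center) @ rot.as_matrix().T + center
    coords[atoms] = sub + translation


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - measure-zero
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def propose_rigid(
    coords: np.ndarray,
    atoms: np.ndarray,
    rng: np.random.Generator,
    max_trans: float,
    max_rot: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Symmetric rigid-body proposal, in place.

    Translation uniform within a ball of radius ``max_trans``; rotation by a
    uniform random axis and uniform angle in [0, max_rot] degrees about the
    segment centroid.  Returns (translation, axis, angle, center) so a test
    can apply the exact inverse.
    """
    if max_trans < 0 or max_rot < 0:
        raise ValueError("step limits must be >= 0")
    if max_trans > 0:
        direction = _random_unit(rng)
        radius = max_trans * rng.random() ** (1.0 / 3.0)
        translation = radius * direction
    else:
        translation = np.zeros(3)
    axis = _random_unit(rng)
    angle = rng.uniform(0.0, max_rot) if max_rot > 0 else 0.0
    center = coords[atoms].mean(axis=0)
    rigid_transform(coords, atoms, translation, axis, angle, center=center)
    return translation, axis, angle, center


def _axis_rotation(
    coords: np.ndarray, moving: np.ndarray, b: int, c: int, angle_deg: float
) -> None:
    axis = coords[c] - coords[b]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError(f"degenerate rotation axis: atoms {b} and {c} coincide")
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / norm)
    coords[moving] = (coords[moving] - coords[b]) @ rot.as_matrix().T + coords[b]


def propose_torsion(
    coords: np.ndarray,
    moving: np.ndarray,
    axis: tuple[int, int],
    rng: np.random.Generator,
    max_angle: float,
) -> float:
    """Rotate ``moving`` about the bond axis by a uniform angle in
    [-max_angle, +max_angle] degrees, in place.  Bond lengths and bond angles
    of atoms outside the moving set are untouched; within it the transform is
    rigid.  Returns the sampled angle."""
    angle = rng.uniform(-max_angle, max_angle) if max_angle > 0 else 0.0
    if angle != 0.0:
        _axis_rotation(coords, moving, axis[0], axis[1], angle)
    return angle


def propose_bend(
    coords: np.ndarray,
    moving: np.ndarray,
    triple: tuple[int, int, int],
    rng: np.random.Generator,
    max_angle: float,
) -> float:
    """Bend-angle move: rotate ``moving`` about the axis through the central
    atom perpendicular to the a-b-c plane.  Completes the stated natural-move
    vocabulary; unused by the bundled case studies."""
    a, b, c = triple
    normal = np.cross(coords[a] - coords[b], coords[c] - coords[b])
    n = np.linalg.norm(normal)
    if n < 1e-9:
        raise ValueError("degenerate bend: collinear atoms")
    angle = rng.uniform(-max_angle, max_angle) if max_angle > 0 else 0.0
    if angle != 0.0:
        rot = Rotation.from_rotvec(np.radians(angle) * normal / n)
        coords[moving] = (coords[moving] - coords[b]) @ rot.as_matrix().T + coords[b]
    return angle


# --------------------------------------------------------------------------
# move-set construction
# --------------------------------------------------------------------------


def _bond_length_map(conf: Conformation) -> dict[tuple[int, int], float]:
    table = {}
    for (i, j), r in zip(conf.bonds, conf.bond_r0):
        table[(int(i), int(j))] = float(r)
        table[(int(j), int(i))] = float(r)
    return table


def _mz_atom_indices(conf: Conformation, mz: MoltenZone) -> list[int]:
    """Backbone chain atoms through a molten zone, in chain order."""
    if mz.kind == "residue":
        return [conf.atom_index(mz.chain, r, "CA") for r in sorted(mz.residues)]
    return [conf.atom_index(mz.chain, r, a) for r, a in mz.atoms]


def _closure_problem(conf: Conformation, mz: MoltenZone, bond_map) -> ClosureProblem:
    mobile = _mz_atom_indices(conf, mz)
    mobile_set = set(mobile)

    if mz.kind == "residue":
        # backbone runs through the CA trace: anchors are the CA sites of the
        # segment-edge residues on either side of the zone
        anchor_pre = conf.atom_index(mz.chain, min(mz.residues) - 1, "CA")
        anchor_post = conf.atom_index(mz.chain, max(mz.residues) + 1, "CA")
    else:

        def outside_neighbor(atom: int, exclude: int | None) -> int:
            for (i, j), _ in bond_map.items():
                if i == atom and j not in mobile_set and j != exclude:
                    return j
            raise ValueError(f"molten zone {mz.id}: no anchor bonded to atom {atom}")

        anchor_pre = outside_neighbor(mobile[0], None)
        anchor_post = outside_neighbor(mobile[-1], anchor_pre)
    chain = np.array([anchor_pre] + mobile + [anchor_post], dtype=int)
    r0 = []
    for i, j in zip(chain, chain[1:]):
        key = (int(i), int(j))
        if key not in bond_map:
            raise ValueError(f"molten zone {mz.id}: atoms {i}-{j} are not bonded")
        r0.append(bond_map[key])
    riders: tuple[tuple[int, ...], ...] = ()
    if mz.kind == "residue":
        groups = []
        for r in sorted(mz.residues):
            res_atoms = conf.residue_atoms(mz.chain, r)
            ca = conf.atom_index(mz.chain, r, "CA")
            groups.append(tuple(int(a) for a in res_atoms if a != ca))
        riders = tuple(groups)
    return ClosureProblem(mz_id=mz.id, chain=chain, bond_r0=np.array(r0), riders=riders)


def build_moveset(
    eff: EffectiveDecomposition,
    conf: Conformation,
    steps: StepConfig | None = None,
) -> MoveSet:
    """Construct the move set a test case implies.

    One rigid-body generator per effective segment (fused segments share
    one), one torsion generator per active torsion; inactive degrees of
    freedom get none.
    """
    steps = steps or StepConfig()
    bond_map = _bond_length_map(conf)

    # atoms claimed by active atom-level zones never move rigidly with a segment
    claimed: set[int] = set()
    interior_mzs: list[MoltenZone] = []
    terminal_by_segment: dict[str, list[MoltenZone]] = {}
    for mz in eff.active_mzs:
        if mz.terminal:
            flank = next(f for f in mz.flanking if f is not None)
            terminal_by_segment.setdefault(flank, []).append(mz)
        else:
            interior_mzs.append(mz)
            if mz.kind == "atom":
                claimed.update(_mz_atom_indices(conf, mz))

    closure_cache = {mz.id: _closure_problem(conf, mz, bond_map) for mz in interior_mzs}

    generators: list[MoveGenerator] = []
    for seg in eff.effective_segments:
        atoms: list[int] = []
        for r in seg.residues:
            atoms.extend(int(a) for a in conf.residue_atoms(seg.chain, r) if int(a) not in claimed)
        for r, name in seg.extra_atoms:
            atoms.append(conf.atom_index(seg.chain, r, name))
        for seg_id in seg.segment_ids:
            for mz in terminal_by_segment.get(seg_id, ()):
                if mz.kind == "residue":
                    for r in mz.residues:
                        atoms.extend(int(a) for a in conf.residue_atoms(mz.chain, r))
                else:
                    atoms.extend(_mz_atom_indices(conf, mz))
        closures = tuple(
            closure_cache[mz.id]
            for mz in interior_mzs
            if set(mz.flanking) & set(seg.segment_ids)
        )
        generators.append(
            MoveGenerator(
                kind="rigid",
                label=seg.id,
                atoms=np.unique(atoms),
                max_trans=steps.max_trans,
                max_rot=steps.max_rot,
                closures=closures,
            )
        )

    for tor in eff.active_torsions:
        b = conf.atom_index(tor.chain, *_ref(tor.axis_atoms[1]))
        c = conf.atom_index(tor.chain, *_ref(tor.axis_atoms[2]))
        moving = np.array([conf.atom_index(tor.chain, *_ref(m)) for m in tor.moving])
        generators.append(
            MoveGenerator(
                kind="torsion",
                label=tor.id,
                atoms=moving,
                max_rot=steps.max_torsion,
                axis=(b, c),
            )
        )

    return MoveSet(generators=generators)


def _ref(atom_ref: tuple[int, str]) -> tuple[int, str]:
    res, name = atom_ref
    return int(res), name
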