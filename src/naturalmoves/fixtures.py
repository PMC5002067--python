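"""Deterministic synthetic structures: ideal helices, a toy two-helix
binding groove, and an idealized B-DNA duplex with optional
5-hydroxymethylcytosine (5hmC) marks.

These fixtures stand in for the crystal structures a production study would
start from.  They are geometric idealizations: every generator is free of
randomness, every bond's "ideal" length is its as-built length, and each
fixture ships with a canonical decomposition so the full protocol can run on
it end to end.

Toy-groove layout (non-authoritative, chosen for this miniature analogue):
helix A carries segments A1, A2 separated by molten zone MZ1 (the "alpha1-1"
kink) and helix B carries B1, B2, B3 separated by MZ2 ("beta1-1") and MZ3
("beta1-2"); one permanently active terminal zone caps each helix end so the
outer segments move freely.  A rigid sheet chain "S" below the helices is a
fixed environment outside the decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decomposition import (
    Chain,
    Decomposition,
    MoltenZone,
    Segment,
    StructureIndex,
    Toggle,
    TorsionDOF,
)
from .structure import Conformation, coarse_grain_protein

__all__ = [
    "make_ideal_helix",
    "make_toy_groove",
    "ToyGroove",
    "make_bdna",
    "make_bdna_decomposition",
    "basepairs",
    "BASE_TEMPLATES",
    "GLYCOSIDIC",
]

# --------------------------------------------------------------------------
# ideal alpha helix (all-atom backbone stub: N, CA, C, CB)
# --------------------------------------------------------------------------


def make_ideal_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    chain: str = "A",
    res_name: str = "ALA",
) -> Conformation:
    """CA trace on ideal alpha-helical parameters (rise 1.5 A, twist 100 deg,
    radius 2.3 A), decorated with N, C and CB stubs so the result can be
    coarse-grained.  The helix axis is z; residue 1's CA sits at the origin.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    names, resids, chains, resnames, elements, coords = [], [], [], [], [], []

    def cyl(r: float, theta_deg: float, z: float) -> np.ndarray:
        t = math.radians(theta_deg)
        return np.array([r * math.cos(t), r * math.sin(t), z])

    for i in range(n_residues):
        theta = i * twist
        z = i * rise
        sites = (
            ("N", "N", cyl(1.6, theta - 28.0, z - 0.9)),
            ("CA", "C", cyl(radius, theta, z)),
            ("C", "C", cyl(1.6, theta + 28.0, z + 0.9)),
            ("CB", "C", cyl(radius + 1.1, theta + 6.0, z + 0.3)),
        )
        for name, elem, xyz in sites:
            names.append(name)
            resids.append(i + 1)
            chains.append(chain)
            resnames.append(res_name)
            elements.append(elem)
            coords.append(xyz)

    coords = np.array(coords)
    coords -= coords[1]  # CA of residue 1 at origin
    return Conformation(
        atom_name=np.array(names),
        res_id=np.array(resids, dtype=int),
        chain_id=np.array(chains),
        res_name=np.array(resnames),
        element=np.array(elements),
        coords=coords,
        model_kind="all-atom-protein",
    )


# --------------------------------------------------------------------------
# toy two-helix groove
# --------------------------------------------------------------------------


@dataclass
class ToyGroove:
    """Toy groove fixture: cg3 conformation, canonical decomposition and the
    residue ranges between which the groove width is measured."""

    conformation: Conformation
    decomposition: Decomposition
    groove_a: tuple[str, int, int]  # (chain, first res, last res)
    groove_b: tuple[str, int, int]
    separation: float


def _rot_y90(coords: np.ndarray) -> np.ndarray:
    # (x, y, z) -> (z, y, -x): helix axis z -> x
    return np.column_stack([coords[:, 2], coords[:, 1], -coords[:, 0]])


def _split(n: int, parts: int) -> list[int]:
    base, extra = divmod(n, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def make_toy_groove(helix_len: int = 20, separation: float = 12.0) -> ToyGroove:
    """Two antiparallel helices atop a rigid sheet, with the canonical
    five-segment decomposition (A1, A2 / B1, B2, B3) and three togglable
    interior molten zones.

    ``helix_len`` is the length of helix B (chain B); helix A is six residues
    shorter.  ``separation`` is the groove width at construction: after
    assembly chain B is shifted along the inter-helix axis so that the
    measured centre-of-mass distance equals it exactly.
    """
    if helix_len < 14:
        raise ValueError("helix_len must be >= 14")
    len_b = helix_len
    len_a = helix_len - 6

    helix_a = make_ideal_helix(len_a, chain="A")
    helix_b = make_ideal_helix(len_b, chain="B")

    a_xyz = _rot_y90(helix_a.coords)
    b_xyz = _rot_y90(helix_b.coords)
    # antiparallel: rotate helix B by 180 deg about z
    b_xyz = np.column_stack([-b_xyz[:, 0], -b_xyz[:, 1], b_xyz[:, 2]])
    a_xyz[:, 0] -= a_xyz[:, 0].mean()
    b_xyz[:, 0] -= b_xyz[:, 0].mean()
    a_xyz[:, 1] += separation / 2.0
    b_xyz[:, 1] -= separation / 2.0

    # rigid sheet below the helices: 2 x m grid of residues
    m = helix_len
    sheet_names, sheet_res, sheet_xyz = [], [], []
    res = 0
    x0 = -(m - 1) * 3.8 / 2.0
    for row in range(2):
        for col in range(m):
            res += 1
            ca = np.array([x0 + col * 3.8, (row - 0.5) * 4.5, -8.0])
            for name, off in (
                ("N", np.array([-1.2, 0.0, 0.4])),
                ("CA", np.zeros(3)),
                ("C", np.array([1.2, 0.0, 0.4])),
                ("CB", np.array([0.0, 0.0, -1.3])),
            ):
                sheet_names.append(name)
                sheet_res.append(res)
                sheet_xyz.append(ca + off)

    names = np.concatenate([helix_a.atom_name, helix_b.atom_name, np.array(sheet_names)])
    resids = np.concatenate([helix_a.res_id, helix_b.res_id, np.array(sheet_res, dtype=int)])
    chains = np.concatenate(
        [helix_a.chain_id, helix_b.chain_id, np.full(len(sheet_names), "S")]
    )
    resnames = np.concatenate(
        [helix_a.res_name, helix_b.res_name, np.full(len(sheet_names), "ALA")]
    )
    elements = np.concatenate(
        [helix_a.element, helix_b.element, np.array([n[0] for n in sheet_names])]
    )
    coords = np.vstack([a_xyz, b_xyz, np.array(sheet_xyz)])

    allatom = Conformation(
        atom_name=names,
        res_id=resids,
        chain_id=chains,
        res_name=resnames,
        element=elements,
        coords=coords,
        model_kind="all-atom-protein",
    )
    cg = coarse_grain_protein(allatom)

    # groove measured between the central 6 residues of each helix
    mid_a, mid_b = len_a // 2, len_b // 2
    groove_a = ("A", mid_a - 2, mid_a + 3)
    groove_b = ("B", mid_b - 2, mid_b + 3)

    def com(chain: str, lo: int, hi: int) -> np.ndarray:
        mask = (cg.chain_id == chain) & (cg.res_id >= lo) & (cg.res_id <= hi)
        return cg.coords[mask].mean(axis=0)

    # shift chain B so the measured groove width equals `separation` exactly
    ca_com, cb_com = com(*groove_a), com(*groove_b)
    axis = cb_com - ca_com
    width = float(np.linalg.norm(axis))
    cg.coords[cg.chain_id == "B"] += axis / width * (separation - width)

    # decomposition: terminal zones 1 residue, interior zones 2 residues
    la1, la2 = _split(len_a - 4, 2)
    lb1, lb2, lb3 = _split(len_b - 6, 3)
    a1 = Segment("A1", "A", 2, 1 + la1)
    a2 = Segment("A2", "A", a1.tail + 3, len_a - 1)
    b1 = Segment("B1", "B", 2, 1 + lb1)
    b2 = Segment("B2", "B", b1.tail + 3, b1.tail + 2 + lb2)
    b3 = Segment("B3", "B", b2.tail + 3, len_b - 1)
    mzs = (
        MoltenZone("termA-N", "residue", "A", residues=(1,), flanking=(None, "A1"), permanent=True),
        MoltenZone("MZ1", "residue", "A", residues=tuple(range(a1.tail + 1, a2.head)), flanking=("A1", "A2")),
        MoltenZone("termA-C", "residue", "A", residues=(len_a,), flanking=("A2", None), permanent=True),
        MoltenZone("termB-N", "residue", "B", residues=(1,), flanking=(None, "B1"), permanent=True),
        MoltenZone("MZ2", "residue", "B", residues=tuple(range(b1.tail + 1, b2.head)), flanking=("B1", "B2")),
        MoltenZone("MZ3", "residue", "B", residues=tuple(range(b2.tail + 1, b3.head)), flanking=("B2", "B3")),
        MoltenZone("termB-C", "residue", "B", residues=(len_b,), flanking=("B3", None), permanent=True),
    )
    decomp = Decomposition(
        structure=StructureIndex(
            chains=(
                Chain("A", tuple(range(1, len_a + 1))),
                Chain("B", tuple(range(1, len_b + 1))),
            )
        ),
        segments=(a1, a2, b1, b2, b3),
        molten_zones=mzs,
    )
    return ToyGroove(
        conformation=cg,
        decomposition=decomp,
        groove_a=groove_a,
        groove_b=groove_b,
        separation=separation,
    )


# --------------------------------------------------------------------------
# idealized B-DNA duplex
# --------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RES_NAME = {"A": "DA", "G": "DG", "C": "DC", "T": "DT"}

GLYCOSIDIC = {"DA": "N9", "DG": "N9", "DC": "N1", "DT": "N1", "5CM": "N1"}

_RING = 1.40  # ring bond length
_HEX_CENTER = np.array([0.0, 2.85])


def _hex_vertex(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return _HEX_CENTER + _RING * np.array([math.cos(t), math.sin(t)])


def _sub(atom: np.ndarray, center: np.ndarray, dist: float) -> np.ndarray:
    u = atom - center
    return atom + dist * u / np.linalg.norm(u)


def _build_templates() -> dict[str, dict[str, np.ndarray]]:
    """Planar idealized base templates in the base reference frame (z = 0).

    The Watson-Crick atom (pyrimidine N3 / purine N1) sits at (0, 1.45) so
    that flipping the partner frame about x places the two WC atoms 2.9 A
    apart.  Regular-polygon rings; exocyclic substituents point radially
    outward; C1' extends from the glycosidic nitrogen.
    """
    # pyrimidine hexagon: N1-C2-N3-C4-C5-C6
    pyr = {
        "N1": _hex_vertex(30),
        "C2": _hex_vertex(-30),
        "N3": _hex_vertex(-90),
        "C4": _hex_vertex(-150),
        "C5": _hex_vertex(150),
        "C6": _hex_vertex(90),
    }
    dc = dict(pyr)
    dc["O2"] = _sub(pyr["C2"], _HEX_CENTER, 1.25)
    dc["N4"] = _sub(pyr["C4"], _HEX_CENTER, 1.35)
    dt = dict(pyr)
    dt["O2"] = _sub(pyr["C2"], _HEX_CENTER, 1.25)
    dt["O4"] = _sub(pyr["C4"], _HEX_CENTER, 1.25)
    dt["C7"] = _sub(pyr["C5"], _HEX_CENTER, 1.50)
    for tpl in (dc, dt):
        tpl["C1'"] = _sub(tpl["N1"], _HEX_CENTER, 1.47)

    # purine hexagon: N1-C2-N3-C4-C5-C6, five-ring C4-C5-N7-C8-N9
    pur = {
        "N1": _hex_vertex(-90),
        "C2": _hex_vertex(-150),
        "N3": _hex_vertex(150),
        "C4": _hex_vertex(90),
        "C5": _hex_vertex(30),
        "C6": _hex_vertex(-30),
    }
    c4, c5 = pur["C4"], pur["C5"]
    mid = (c4 + c5) / 2.0
    out = mid - _HEX_CENTER
    out /= np.linalg.norm(out)
    apothem = _RING / (2.0 * math.tan(math.pi / 5.0))
    pc = mid + out * apothem  # pentagon centre
    circum = _RING / (2.0 * math.sin(math.pi / 5.0))

    def pent_angle(p: np.ndarray) -> float:
        v = p - pc
        return math.atan2(v[1], v[0])

    a4, a5 = pent_angle(c4), pent_angle(c5)
    step = a5 - a4
    step -= 2 * math.pi * round(step / (2 * math.pi))  # wrap to (-pi, pi]

    def pent_vertex(k: int) -> np.ndarray:
        t = a5 + k * step
        return pc + circum * np.array([math.cos(t), math.sin(t)])

    pur["N7"], pur["C8"], pur["N9"] = pent_vertex(1), pent_vertex(2), pent_vertex(3)

    dg = dict(pur)
    dg["O6"] = _sub(pur["C6"], _HEX_CENTER, 1.25)
    dg["N2"] = _sub(pur["C2"], _HEX_CENTER, 1.35)
    da = dict(pur)
    da["N6"] = _sub(pur["C6"], _HEX_CENTER, 1.35)
    for tpl in (dg, da):
        tpl["C1'"] = _sub(tpl["N9"], pc, 1.47)

    out3d = {}
    for name, tpl in (("DC", dc), ("DT", dt), ("DG", dg), ("DA", da)):
        out3d[name] = {a: np.array([p[0], p[1], 0.0]) for a, p in tpl.items()}
    return out3d


BASE_TEMPLATES = _build_templates()

#: template atoms used to fit base reference frames (ring atoms only)
FRAME_ATOMS = {
    "DC": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "DT": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "5CM": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "DG": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "DA": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
}

_RING_BONDS = {
    "pyr": [("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1")],
    "pur": [
        ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
        ("C5", "N7"), ("N7", "C8"), ("C8", "N9"), ("N9", "C4"),
    ],
}
_SUB_BONDS = {
    "DC": [("C2", "O2"), ("C4", "N4"), ("N1", "C1'")],
    "DT": [("C2", "O2"), ("C4", "O4"), ("C5", "C7"), ("N1", "C1'")],
    "DG": [("C6", "O6"), ("C2", "N2"), ("N9", "C1'")],
    "DA": [("C6", "N6"), ("N9", "C1'")],
}

# backbone atoms on a compressed helical path; offsets expressed in the base
# frame so every nucleotide is built identically (see docs/methods.md)
_BB_RADIUS = 9.0
_BB_T = {"P": 0.04, "O5'": 0.20, "C5'": 0.36, "C4'": 0.52, "C3'": 0.68, "O3'": 0.84}
# radial zigzag gives the inter-nucleotide closure chain slack to absorb moves
_BB_DR = {"P": 0.8, "O5'": -0.6, "C5'": 0.7, "C4'": -0.5, "C3'": 0.6, "O3'": -0.7}
_BB_ORDER = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
_BB_BONDS = [("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "C3'"), ("C3'", "O3'"), ("C4'", "C1'")]


def _bb_offset(atom: str, rise: float, twist: float) -> np.ndarray:
    t = _BB_T[atom]
    r = _BB_RADIUS + _BB_DR[atom]
    ang = math.radians(twist * (t - 1.0))
    return np.array([r * math.cos(ang), r * math.sin(ang), rise * (t - 1.0)])


def _rz(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP = np.diag([1.0, -1.0, -1.0])


def make_bdna(
    sequence: str,
    mods: tuple[tuple[str, int, str], ...] = (),
    drop_terminal_bp: int = 0,
    rise: float = 3.38,
    twist: float = 36.0,
) -> Conformation:
    """Fiber-model B-DNA duplex from a sequence (strand A, 5'->3').

    The complementary strand B is generated automatically; both chains are
    numbered 1..n in their own 5'->3' direction, so basepair i pairs A:i with
    B:(n+1-i).  Base atoms are idealized planar templates placed on exactly
    zero basepair parameters; backbone atoms lie on a compressed helical path.

    ``mods`` lists 5hmC marks as ``(chain, residue, orientation)`` with
    orientation ``"toward"`` (hydroxyl O oriented toward the 3'-adjacent
    guanine's O6, the configuration seen crystallographically) or ``"away"``.
    ``drop_terminal_bp`` removes that many basepairs from each duplex end
    before building (residues renumber from 1).
    """
    sequence = sequence.upper()
    if any(ch not in "ACGT" for ch in sequence):
        bad = next(ch for ch in sequence if ch not in "ACGT")
        raise ValueError(f"invalid DNA base {bad!r}: sequence must be A/C/G/T")
    if drop_terminal_bp:
        if 2 * drop_terminal_bp >= len(sequence):
            raise ValueError("drop_terminal_bp removes the whole duplex")
        sequence = sequence[drop_terminal_bp:-drop_terminal_bp]
    n = len(sequence)

    names, resids, chains, resnames, elements, coords = [], [], [], [], [], []

    def add_nt(chain: str, res: int, base: str, R: np.ndarray, origin: np.ndarray) -> None:
        rname = _RES_NAME[base]
        tpl = BASE_TEMPLATES[rname]
        for atom in _BB_ORDER:
            names.append(atom)
            resids.append(res)
            chains.append(chain)
            resnames.append(rname)
            elements.append(atom[0])
            coords.append(origin + R @ _bb_offset(atom, rise, twist))
        for atom, local in tpl.items():
            names.append(atom)
            resids.append(res)
            chains.append(chain)
            resnames.append(rname)
            elements.append(atom[0].replace("'", ""))
            coords.append(origin + R @ local)

    # strand A: residue i == basepair i
    for i in range(1, n + 1):
        theta = (i - 1) * twist
        origin = np.array([0.0, 0.0, (i - 1) * rise])
        add_nt("A", i, sequence[i - 1], _rz(theta), origin)
    # strand B: residue j == basepair n+1-j, frame flipped about the pair x axis
    for j in range(1, n + 1):
        i = n + 1 - j
        theta = (i - 1) * twist
        origin = np.array([0.0, 0.0, (i - 1) * rise])
        add_nt("B", j, _COMPLEMENT[sequence[i - 1]], _rz(theta) @ _FLIP, origin)

    conf = Conformation(
        atom_name=np.array(names, dtype="U6"),
        res_id=np.array(resids, dtype=int),
        chain_id=np.array(chains, dtype="U4"),
        res_name=np.array(resnames, dtype="U6"),  # wide enough for the 5CM mark
        element=np.array(elements, dtype="U2"),
        coords=np.array(coords),
        model_kind="all-atom-dna",
    )

    for chain, res, orientation in mods:
        _add_5hm_mark(conf, chain, res, orientation)

    conf.bonds, conf.bond_r0 = _dna_bonds(conf)
    return conf


def _add_5hm_mark(conf: Conformation, chain: str, res: int, orientation: str) -> None:
    if orientation not in ("toward", "away"):
        raise ValueError(f"unknown hydroxyl orientation {orientation!r}")
    idx = conf.residue_atoms(chain, res)
    if len(idx) == 0:
        raise KeyError(f"no residue {chain}:{res}")
    if conf.res_name[idx[0]] != "DC":
        raise ValueError(f"5hmC mark requires a cytosine at {chain}:{res}, found {conf.res_name[idx[0]]}")
    nxt = conf.residue_atoms(chain, res + 1)
    if len(nxt) == 0 or conf.res_name[nxt[0]] != "DG":
        raise ValueError(f"5hmC orientation needs a 3'-adjacent guanine after {chain}:{res}")

    c5 = conf.coords[conf.atom_index(chain, res, "C5")]
    c4 = conf.coords[conf.atom_index(chain, res, "C4")]
    c6 = conf.coords[conf.atom_index(chain, res, "C6")]
    o6 = conf.coords[conf.atom_index(chain, res + 1, "O6")]

    ring_center = (c4 + c6) / 2.0  # local in-plane reference
    u = c5 - ring_center
    u /= np.linalg.norm(u)
    normal = np.cross(c4 - c5, c6 - c5)
    normal /= np.linalg.norm(normal)
    v = np.cross(normal, u)

    c5m = c5 + 1.50 * u
    # hydroxyl O on a 70-degree cone about the C5-C5M axis; pick the azimuth
    # closest to (or, for the control, farthest from) the 3'-G O6
    tilt = math.radians(70.0)
    best, best_d = None, None
    for k in range(720):
        psi = 2 * math.pi * k / 720
        cand = c5m + 1.43 * (
            math.cos(tilt) * u + math.sin(tilt) * (math.cos(psi) * v + math.sin(psi) * normal)
        )
        dist = np.linalg.norm(cand - o6)
        if best_d is None:
            best, best_d = cand, dist
            continue
        if (dist < best_d) if orientation == "toward" else (dist > best_d):
            best, best_d = cand, dist
    o5 = best
    if orientation == "toward":
        ho5 = o5 + 0.96 * (o6 - o5) / np.linalg.norm(o6 - o5)
    else:
        ho5 = o5 + 0.96 * (o5 - c5m) / np.linalg.norm(o5 - c5m)

    ins = idx[-1] + 1
    for name, xyz, elem in (("C5M", c5m, "C"), ("O5", o5, "O"), ("HO5", ho5, "H")):
        conf.atom_name = np.insert(conf.atom_name, ins, name)
        conf.res_id = np.insert(conf.res_id, ins, res)
        conf.chain_id = np.insert(conf.chain_id, ins, chain)
        conf.res_name = np.insert(conf.res_name, ins, "5CM")
        conf.element = np.insert(conf.element, ins, elem)
        conf.coords = np.insert(conf.coords, ins, xyz, axis=0)
        ins += 1
    conf.res_name[conf.residue_atoms(chain, res)] = "5CM"
    conf._index = None


def _dna_bonds(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    bonds: list[tuple[int, int]] = []

    def add(chain: str, res: int, a: str, b: str, res_b: int | None = None) -> None:
        bonds.append(
            (conf.atom_index(chain, res, a), conf.atom_index(chain, res_b or res, b))
        )

    for chain in dict.fromkeys(conf.chain_id):
        residues = conf.chain_residues(chain)
        for res in residues:
            rname = conf.res_name[conf.residue_atoms(chain, res)[0]]
            kind = "pur" if rname in ("DA", "DG") else "pyr"
            for a, b in _BB_BONDS + _RING_BONDS[kind] + _SUB_BONDS.get(rname, _SUB_BONDS["DC"]):
                add(chain, res, a, b)
            add(chain, res, "C1'", GLYCOSIDIC[rname])
            if rname == "5CM":
                for a, b in (("C5", "C5M"), ("C5M", "O5"), ("O5", "HO5")):
                    add(chain, res, a, b)
        for r0, r1 in zip(residues, residues[1:]):
            add(chain, r0, "O3'", "P", res_b=r1)

    arr = np.array(sorted(set(bonds)), dtype=int)
    r0 = np.linalg.norm(conf.coords[arr[:, 0]] - conf.coords[arr[:, 1]], axis=1)
    return arr, r0


def basepairs(conf: Conformation) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Canonical basepairs of a duplex built by :func:`make_bdna`."""
    res_a = conf.chain_residues("A")
    n = len(res_a)
    return [(("A", int(i)), ("B", int(n + 1 - i))) for i in res_a]


_MZ_ATOMS = ("O3'", "P", "O5'", "C5'")


def make_bdna_decomposition(
    conf: Conformation,
    marks: tuple[tuple[str, int], ...] = (),
) -> Decomposition:
    """Canonical nucleic-acid decomposition: every nucleotide its own segment
    (so there are no residue-level molten zones), atom-level molten zones on
    the inter-nucleotide backbone (O3'-P-O5'-C5'), and -- for each 5hmC
    mark -- two hydroxyl torsions.

    Only the zones between a mark and its 3'-adjacent guanine are togglable;
    all other junction zones are permanently active.  The decomposition
    vector follows the DNA convention: bit 1 toggles all marks' C5-C5M
    torsions jointly, bit 2 the C5M-O5 torsions, bit 3 the mark/G zones.
    """
    mark_set = {(c, int(r)) for c, r in marks}
    chains = []
    segments = []
    mzs = []
    torsions = []
    mark_mz_ids = []
    phi1_ids, phi2_ids = [], []

    for chain in (str(c) for c in dict.fromkeys(conf.chain_id)):
        residues = conf.chain_residues(chain)
        chains.append(Chain(chain, tuple(int(r) for r in residues)))
        for res in residues:
            segments.append(Segment(f"{chain}{res}", chain, int(res), int(res)))
        for r0, r1 in zip(residues, residues[1:]):
            mz_id = f"mz{chain}{r0}-{r1}"
            togglable = (chain, int(r0)) in mark_set
            mzs.append(
                MoltenZone(
                    mz_id,
                    "atom",
                    chain,
                    atoms=(
                        (int(r0), "O3'"),
                        (int(r1), "P"),
                        (int(r1), "O5'"),
                        (int(r1), "C5'"),
                    ),
                    flanking=(f"{chain}{r0}", f"{chain}{r1}"),
                    permanent=not togglable,
                )
            )
            if togglable:
                mark_mz_ids.append(mz_id)

    for chain, res in sorted(mark_set):
        phi1 = TorsionDOF(
            f"phi1-{chain}{res}",
            chain,
            axis_atoms=((res, "C4"), (res, "C5"), (res, "C5M"), (res, "O5")),
            moving=((res, "O5"), (res, "HO5")),
        )
        phi2 = TorsionDOF(
            f"phi2-{chain}{res}",
            chain,
            axis_atoms=((res, "C5"), (res, "C5M"), (res, "O5"), (res, "HO5")),
            moving=((res, "HO5"),),
        )
        torsions.extend([phi1, phi2])
        phi1_ids.append(phi1.id)
        phi2_ids.append(phi2.id)

    toggles = None
    if mark_set:
        toggles = (
            Toggle("phi1", torsion_ids=tuple(phi1_ids)),
            Toggle("phi2", torsion_ids=tuple(phi2_ids)),
            Toggle("mzCG", mz_ids=tuple(mark_mz_ids)),
        )
    return Decomposition(
        structure=StructureIndex(chains=tuple(chains)),
        segments=tuple(segments),
        molten_zones=tuple(mzs),
        torsions=tuple(torsions),
        toggles=toggles,
    )
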