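"""Structure decomposition and binary test-case algebra.

A biopolymer is partitioned into *segments* (contiguous residue runs moved as
rigid bodies) separated by *molten zones* (MZ) -- residues (proteins) or
backbone atoms (nucleic acids) that a chain-closure algorithm rearranges to
absorb chain breaks.  Selected bond torsions may additionally be toggled.

The togglable degrees of freedom define a binary decomposition vector D:
each bit activates (1) or deactivates (0) one toggle.  Deactivating a molten
zone fuses its two flanking segments into a single rigid body; deactivating a
torsion freezes that dihedral.  Every bit pattern is one *test case*, written
as a binary string such as ``"010"``, and the set of all ``2**|D|`` patterns
enumerates the hypotheses a study compares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

__all__ = [
    "Chain",
    "StructureIndex",
    "Segment",
    "MoltenZone",
    "TorsionDOF",
    "Toggle",
    "Decomposition",
    "TestCase",
    "EffectiveSegment",
    "EffectiveDecomposition",
    "ValidationReport",
    "Violation",
    "CombinatorialExplosionError",
    "validate_decomposition",
    "enumerate_test_cases",
    "apply_test_case",
    "parse_testcase_label",
    "format_testcase",
    "dna_filter_testcases",
    "bits_equal",
    "drop_labels",
]

AtomRef = tuple[int, str]  # (residue index, atom name) within a chain


class CombinatorialExplosionError(ValueError):
    """Raised when the number of togglable DOFs exceeds the enumeration cap."""


@dataclass(frozen=True)
class Chain:
    """A chain: identifier plus its (1-based, strictly increasing) residues."""

    id: str
    residues: tuple[int, ...]

    @property
    def head(self) -> int:
        return self.residues[0]

    @property
    def tail(self) -> int:
        return self.residues[-1]


@dataclass(frozen=True)
class StructureIndex:
    """Residue-level index of the sub-system covered by a decomposition.

    Residues not indexed here (e.g. a rigid scaffold chain) are treated as a
    fixed environment: they are never moved and never validated against the
    partition invariant.
    """

    chains: tuple[Chain, ...]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("StructureIndex needs at least one chain")
        seen = set()
        for c in self.chains:
            if c.id in seen:
                raise ValueError(f"duplicate chain id {c.id!r}")
            seen.add(c.id)
            if len(c.residues) < 1:
                raise ValueError(f"chain {c.id!r} is empty")
            if any(b <= a for a, b in zip(c.residues, c.residues[1:])):
                raise ValueError(
                    f"chain {c.id!r}: residue indices must be strictly increasing"
                )

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def residues(self) -> tuple[tuple[str, int], ...]:
        """All (chain id, residue index) pairs in chain order."""
        return tuple((c.id, r) for c in self.chains for r in c.residues)


@dataclass(frozen=True)
class Segment:
    """A contiguous residue range moved as one rigid body."""

    id: str
    chain: str
    head: int
    tail: int
    internal_torsions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.head > self.tail:
            raise ValueError(f"segment {self.id!r}: head > tail")

    def residues(self) -> tuple[int, ...]:
        return tuple(range(self.head, self.tail + 1))


@dataclass(frozen=True)
class MoltenZone:
    """Closure region between segments (or at a chain terminus).

    ``kind`` is ``"residue"`` (whole residues, protein style) or ``"atom"``
    (backbone atoms between two adjacent nucleotide segments).  ``flanking``
    names the up/downstream segments; ``None`` marks a chain terminus, in
    which case the zone is permanently active and simply rides along with its
    single neighbour.  Permanent zones are excluded from the decomposition
    vector.
    """

    id: str
    kind: str  # "residue" | "atom"
    chain: str
    residues: tuple[int, ...] = ()
    atoms: tuple[AtomRef, ...] = ()
    flanking: tuple[str | None, str | None] = (None, None)
    permanent: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("residue", "atom"):
            raise ValueError(f"molten zone {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "residue" and not self.residues:
            raise ValueError(f"molten zone {self.id!r}: residue-level zone needs residues")
        if self.kind == "atom" and not self.atoms:
            raise ValueError(f"molten zone {self.id!r}: atom-level zone needs atoms")

    @property
    def terminal(self) -> bool:
        return None in self.flanking


@dataclass(frozen=True)
class TorsionDOF:
    """A togglable dihedral: 4 axis atoms a-b-c-d, rotation about b-c.

    ``moving`` lists the atoms carried by the rotation; it must exclude the
    first two axis atoms.
    """

    id: str
    chain: str
    axis_atoms: tuple[AtomRef, AtomRef, AtomRef, AtomRef]
    moving: tuple[AtomRef, ...]

    def __post_init__(self) -> None:
        if len(self.axis_atoms) != 4:
            raise ValueError(f"torsion {self.id!r}: need exactly 4 axis atoms")
        if set(self.axis_atoms[:2]) & set(self.moving):
            raise ValueError(f"torsion {self.id!r}: moving set overlaps fixed axis atoms")


@dataclass(frozen=True)
class Toggle:
    """One bit of the decomposition vector.

    A toggle may control several molten zones and/or torsions at once (e.g.
    symmetric epigenetic marks on both strands of a palindromic duplex toggle
    as a single hypothesis bit).
    """

    label: str
    mz_ids: tuple[str, ...] = ()
    torsion_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.mz_ids and not self.torsion_ids:
            raise ValueError(f"toggle {self.label!r} controls nothing")


@dataclass(frozen=True)
class TestCase:
    """A binary vector over the decomposition's toggles, e.g. label '010'."""

    __test__ = False  # not a pytest class, despite the domain name

    bits: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("test-case bits must be 0 or 1")
        if self.label != "".join(str(b) for b in self.bits):
            raise ValueError("label does not match bits")


@dataclass(frozen=True)
class EffectiveSegment:
    """A maximal run of segments fused by deactivated molten zones."""

    id: str
    segment_ids: tuple[str, ...]
    chain: str
    residues: tuple[int, ...]
    # atoms absorbed from deactivated atom-level molten zones
    extra_atoms: tuple[AtomRef, ...] = ()


@dataclass(frozen=True)
class EffectiveDecomposition:
    effective_segments: tuple[EffectiveSegment, ...]
    active_mzs: tuple[MoltenZone, ...]
    active_torsions: tuple[TorsionDOF, ...]
    testcase: TestCase


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "valid decomposition"
        return "\n".join(f"[{v.kind}] {v.message}" for v in self.violations)


@dataclass(frozen=True)
class Decomposition:
    """Full partition of a structure into segments, molten zones and torsions.

    ``toggles`` fixes the bit order of the decomposition vector.  If omitted
    it defaults to one bit per non-permanent molten zone (chain order) followed
    by one bit per torsion (declaration order).
    """

    structure: StructureIndex
    segments: tuple[Segment, ...]
    molten_zones: tuple[MoltenZone, ...] = ()
    torsions: tuple[TorsionDOF, ...] = ()
    toggles: tuple[Toggle, ...] | None = None

    def segment(self, seg_id: str) -> Segment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(f"no segment {seg_id!r}")

    def molten_zone(self, mz_id: str) -> MoltenZone:
        for m in self.molten_zones:
            if m.id == mz_id:
                return m
        raise KeyError(f"no molten zone {mz_id!r}")

    def torsion(self, t_id: str) -> TorsionDOF:
        for t in self.torsions:
            if t.id == t_id:
                return t
        raise KeyError(f"no torsion {t_id!r}")

    def default_toggles(self) -> tuple[Toggle, ...]:
        mz_toggles = tuple(
            Toggle(label=m.id, mz_ids=(m.id,))
            for m in self.molten_zones
            if not m.permanent and not m.terminal
        )
        phi_toggles = tuple(Toggle(label=t.id, torsion_ids=(t.id,)) for t in self.torsions)
        return mz_toggles + phi_toggles

    @property
    def active_toggles(self) -> tuple[Toggle, ...]:
        return self.toggles if self.toggles is not None else self.default_toggles()

    @property
    def n_bits(self) -> int:
        return len(self.active_toggles)


def validate_decomposition(d: Decomposition) -> ValidationReport:
    """Check the partition and adjacency invariants of a decomposition.

    The union of segment residues and residue-level molten-zone residues must
    equal the indexed residues, with no residue claimed twice ("overlap") and
    none left out ("orphan").  Molten zones must name existing flanking
    segments, and togglable zones must sit between two segments.
    """
    violations: list[Violation] = []
    chain_ids = {c.id for c in d.structure.chains}

    owner: dict[tuple[str, int], str] = {}

    def claim(chain: str, res: int, who: str) -> None:
        key = (chain, res)
        if key in owner:
            violations.append(
                Violation("overlap", f"residue {chain}:{res} in both {owner[key]!r} and {who!r}")
            )
        else:
            owner[key] = who

    seg_ids = set()
    for s in d.segments:
        if s.id in seg_ids:
            violations.append(Violation("duplicate", f"segment id {s.id!r} repeated"))
        seg_ids.add(s.id)
        if s.chain not in chain_ids:
            violations.append(Violation("chain", f"segment {s.id!r} on unknown chain {s.chain!r}"))
            continue
        chain = d.structure.chain(s.chain)
        for r in s.residues():
            if r not in chain.residues:
                violations.append(
                    Violation("range", f"segment {s.id!r} residue {r} outside chain {s.chain!r}")
                )
            else:
                claim(s.chain, r, s.id)

    for m in d.molten_zones:
        for fl in m.flanking:
            if fl is not None and fl not in seg_ids:
                violations.append(
                    Violation("flank", f"molten zone {m.id!r} flanks unknown segment {fl!r}")
                )
        if m.kind == "residue":
            if m.chain not in chain_ids:
                violations.append(
                    Violation("chain", f"molten zone {m.id!r} on unknown chain {m.chain!r}")
                )
                continue
            chain = d.structure.chain(m.chain)
            for r in m.residues:
                if r not in chain.residues:
                    violations.append(
                        Violation("range", f"molten zone {m.id!r} residue {r} outside chain {m.chain!r}")
                    )
                else:
                    claim(m.chain, r, m.id)
        if not m.permanent and m.terminal:
            violations.append(
                Violation("terminal", f"togglable molten zone {m.id!r} lacks two flanking segments")
            )

    for chain, res in d.structure.residues:
        if (chain, res) not in owner:
            violations.append(Violation("orphan", f"residue {chain}:{res} in no segment or molten zone"))

    toggles = d.active_toggles
    labels = set()
    for t in toggles:
        if t.label in labels:
            violations.append(Violation("duplicate", f"toggle label {t.label!r} repeated"))
        labels.add(t.label)
        for mid in t.mz_ids:
            try:
                m = d.molten_zone(mid)
            except KeyError:
                violations.append(Violation("toggle", f"toggle {t.label!r} names unknown molten zone {mid!r}"))
                continue
            if m.permanent or m.terminal:
                violations.append(
                    Violation("toggle", f"toggle {t.label!r} controls permanent/terminal zone {mid!r}")
                )
        for tid in t.torsion_ids:
            try:
                d.torsion(tid)
            except KeyError:
                violations.append(Violation("toggle", f"toggle {t.label!r} names unknown torsion {tid!r}"))

    return ValidationReport(tuple(violations))


def _label(bits: Sequence[int]) -> str:
    return "".join(str(b) for b in bits)


def enumerate_test_cases(
    d: Decomposition,
    torsion_groups: Sequence[Sequence[str]] | None = None,
    cap: int = 20,
) -> list[TestCase]:
    """All ``2**|D|`` test cases in lexicographic order of their bit strings.

    ``torsion_groups`` optionally merges several torsions into a single bit
    (each group replaces its members' individual toggles, in the position of
    the group's first member).
    """
    toggles = list(d.active_toggles)
    if torsion_groups:
        for group in torsion_groups:
            group = tuple(group)
            members = [t for t in toggles if t.torsion_ids and set(t.torsion_ids) <= set(group)]
            if not members:
                raise KeyError(f"torsion group {group!r} matches no toggles")
            first = min(toggles.index(t) for t in members)
            merged = Toggle(
                label="+".join(group),
                torsion_ids=tuple(tid for t in members for tid in t.torsion_ids),
            )
            toggles = [t for t in toggles if t not in members]
            toggles.insert(first, merged)
    n = len(toggles)
    if n > cap:
        raise CombinatorialExplosionError(
            f"combinatorial explosion: {n} togglable DOFs would give 2**{n} test cases (cap {cap})"
        )
    cases = []
    for bits in itertools.product((0, 1), repeat=n):
        cases.append(TestCase(bits=bits, label=_label(bits)))
    return cases


def apply_test_case(d: Decomposition, t: TestCase) -> EffectiveDecomposition:
    """Fuse segments across deactivated molten zones and mark active DOFs.

    A deactivated zone (bit 0) merges its flanking segments -- transitively,
    so a run of segments joined by deactivated zones becomes one effective
    segment whose internal arrangement is held rigid.  The zone's own residues
    (or atoms) join the fused body.  Active zones (bit 1) remain closure
    regions, and permanent/terminal zones are always active.
    """
    toggles = d.active_toggles
    if len(t.bits) != len(toggles):
        raise ValueError(
            f"test case has {len(t.bits)} bits but decomposition has {len(toggles)} toggles"
        )

    state: dict[str, int] = {}  # mz id -> bit
    torsion_state: dict[str, int] = {}
    for bit, tog in zip(t.bits, toggles):
        for mid in tog.mz_ids:
            state[mid] = bit
        for tid in tog.torsion_ids:
            torsion_state[tid] = bit

    # union-find over segment ids
    parent = {s.id: s.id for s in d.segments}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    deactivated: list[MoltenZone] = []
    for m in d.molten_zones:
        if m.permanent or m.terminal:
            continue
        bit = state.get(m.id, 1)  # untoggled internal zones stay active
        if bit == 0:
            a, b = m.flanking
            union(a, b)
            deactivated.append(m)

    groups: dict[str, list[Segment]] = {}
    for s in d.segments:
        groups.setdefault(find(s.id), []).append(s)

    order = {s.id: i for i, s in enumerate(d.segments)}
    eff_segments = []
    for _, members in sorted(groups.items(), key=lambda kv: min(order[s.id] for s in kv[1])):
        members = sorted(members, key=lambda s: order[s.id])
        chain = members[0].chain
        residues = sorted({r for s in members for r in s.residues()})
        member_ids = {s.id for s in members}
        extra: list[AtomRef] = []
        for m in deactivated:
            if set(m.flanking) <= member_ids:
                if m.kind == "residue":
                    residues = sorted(set(residues) | set(m.residues))
                else:
                    extra.extend(m.atoms)
        eff_segments.append(
            EffectiveSegment(
                id="+".join(s.id for s in members),
                segment_ids=tuple(s.id for s in members),
                chain=chain,
                residues=tuple(residues),
                extra_atoms=tuple(extra),
            )
        )

    active_mzs = tuple(
        m
        for m in d.molten_zones
        if m.permanent or m.terminal or state.get(m.id, 1) == 1
    )
    active_torsions = tuple(t_ for t_ in d.torsions if torsion_state.get(t_.id, 0) == 1)
    return EffectiveDecomposition(
        effective_segments=tuple(eff_segments),
        active_mzs=active_mzs,
        active_torsions=active_torsions,
        testcase=t,
    )


def parse_testcase_label(s: str, d: Decomposition) -> TestCase:
    """Parse a binary string like '010' against a decomposition's bit length."""
    if any(ch not in "01" for ch in s):
        raise ValueError(f"invalid test-case label {s!r}: only '0'/'1' allowed")
    if len(s) != d.n_bits:
        raise ValueError(
            f"test-case label {s!r} has {len(s)} bits, decomposition expects {d.n_bits}"
        )
    return TestCase(bits=tuple(int(ch) for ch in s), label=s)


def format_testcase(t: TestCase) -> str:
    return t.label


Rule = Callable[[TestCase], bool]


def bits_equal(*positions: int) -> Rule:
    """Rule: keep only cases whose bits at the given positions agree."""

    def rule(t: TestCase) -> bool:
        vals = {t.bits[p] for p in positions}
        return len(vals) <= 1

    return rule


def drop_labels(labels: Iterable[str]) -> Rule:
    """Rule: drop the named binary strings."""
    dropped = set(labels)

    def rule(t: TestCase) -> bool:
        return t.label not in dropped

    return rule


def dna_filter_testcases(cases: Sequence[TestCase], rules: Sequence[Rule]) -> list[TestCase]:
    """Filter test cases by declarative rules (all must pass); order preserved."""
    return [c for c in cases if all(rule(c) for rule in rules)]
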