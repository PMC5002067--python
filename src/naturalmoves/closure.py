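"""Chain closure through molten zones, and bonded-geometry validation.

After a rigid segment move the backbone through each active molten zone is
broken; closure repositions only the zone's mobile atoms so that every zone
bond returns to its ideal length while both anchor atoms (the fixed segment
edges) are untouched.  The solver is an iterative forward/backward reaching
scheme over the zone's backbone chain: each sweep walks the chain once from
either end, resetting bond lengths exactly, so the cost is linear in the
number of mobile atoms and the result is deterministic.  Auxiliary atoms
riding on a mobile backbone site (the N and sidechain sites of a
coarse-grained residue) are translated with it.

If the anchors are separated beyond the zone's maximal extension -- or the
solver fails to reach tolerance within its iteration budget -- the closure
is *infeasible* and the caller must reject the enclosing Monte Carlo move;
a distorted structure is never returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Conformation

__all__ = [
    "ClosureProblem",
    "ClosureInfeasible",
    "close_chain",
    "validate_geometry",
    "GeometryReport",
]


class ClosureInfeasible(Exception):
    """Signals that the anchors cannot be bridged; callers reject the move."""


@dataclass
class ClosureProblem:
    """A molten-zone closure task over atom indices into a coordinate array.

    ``chain`` lists the backbone atoms through the zone in order:
    ``chain[0]`` and ``chain[-1]`` are the fixed anchors (segment edge
    atoms); everything between is mobile.  ``bond_r0[i]`` is the ideal
    length of the bond ``chain[i]``-``chain[i+1]``.  ``riders[j]`` lists
    atoms translated along with mobile atom ``chain[1+j]``.
    """

    mz_id: str
    chain: np.ndarray  # (m+2,) atom indices, anchors at both ends
    bond_r0: np.ndarray  # (m+1,)
    riders: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=int)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        if len(self.chain) < 3:
            raise ValueError("closure chain needs >= 1 mobile atom between two anchors")
        if len(self.bond_r0) != len(self.chain) - 1:
            raise ValueError("need one ideal length per chain bond")
        if self.riders and len(self.riders) != len(self.chain) - 2:
            raise ValueError("riders must align with mobile atoms")

    @property
    def mobile(self) -> np.ndarray:
        return self.chain[1:-1]

    @property
    def all_moved(self) -> np.ndarray:
        extra = [a for group in self.riders for a in group]
        return np.concatenate([self.mobile, np.asarray(extra, dtype=int)]) if extra else self.mobile


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        # degenerate direction; deterministic fallback
        return np.array([1.0, 0.0, 0.0])
    return v / n


def close_chain(
    coords: np.ndarray,
    problem: ClosureProblem,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> None:
    """Close one molten zone in place.

    On success every zone bond is within ``tol`` of its ideal length and the
    anchors are byte-identical.  Raises :class:`ClosureInfeasible` when the
    anchor gap exceeds the chain's maximal extension or the iteration budget
    is exhausted.
    """
    idx = problem.chain
    r0 = problem.bond_r0
    p = coords[idx].copy()
    a0, a1 = p[0], p[-1]
    gap = np.linalg.norm(a1 - a0)
    if gap > r0.sum() + tol:
        raise ClosureInfeasible(
            f"molten zone {problem.mz_id}: anchor gap {gap:.3f} A exceeds reach {r0.sum():.3f} A"
        )
    if len(idx) == 3 and gap + tol < abs(r0[0] - r0[1]):
        raise ClosureInfeasible(
            f"molten zone {problem.mz_id}: anchors too close for bond lengths"
        )

    old_mobile = p[1:-1].copy()

    def errors(q: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.diff(q, axis=0), axis=1)
        return np.abs(d - r0)

    if errors(p).max() <= tol:
        return  # already intact: closure is the identity

    m = len(p)
    for _ in range(max_iter):
        # backward pass: from the downstream anchor toward the start
        p[-1] = a1
        for i in range(m - 2, 0, -1):
            p[i] = p[i + 1] + r0[i] * _unit(p[i] - p[i + 1])
        # forward pass: from the upstream anchor toward the end
        p[0] = a0
        for i in range(1, m - 1):
            p[i] = p[i - 1] + r0[i - 1] * _unit(p[i] - p[i - 1])
        if errors(p).max() <= tol:
            break
    else:
        raise ClosureInfeasible(
            f"molten zone {problem.mz_id}: no closure within {max_iter} sweeps"
        )

    coords[problem.mobile] = p[1:-1]
    for j, group in enumerate(problem.riders):
        if group:
            coords[list(group)] += p[1 + j] - old_mobile[j]


@dataclass
class GeometryReport:
    violations: list[tuple[int, int, float, float]] = field(default_factory=list)
    # (atom_i, atom_j, actual length, ideal length)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "chain intact"
        return "\n".join(
            f"bond {i}-{j}: {d:.4f} A (ideal {r:.4f} A)" for i, j, d, r in self.violations
        )


def validate_geometry(conf: Conformation, tol: float = 1e-3) -> GeometryReport:
    """List every bond deviating from its ideal length by more than ``tol``.

    An empty report certifies chain integrity -- the structural guarantee the
    molten-zone mechanism must maintain across an accepted trajectory.
    """
    report = GeometryReport()
    if len(conf.bonds) == 0:
        return report
    d = np.linalg.norm(conf.coords[conf.bonds[:, 0]] - conf.coords[conf.bonds[:, 1]], axis=1)
    bad = np.abs(d - conf.bond_r0) > tol
    for (i, j), length, ideal in zip(conf.bonds[bad], d[bad], conf.bond_r0[bad]):
        report.violations.append((int(i), int(j), float(length), float(ideal)))
    return report
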