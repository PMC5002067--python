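"""YAML (de)serialization of decompositions and sampler settings.

Schema example::

    chains:
      A: [1, 14]          # head/tail residue numbers
    segments:
      - {id: A1, chain: A, range: [2, 6]}
    molten_zones:
      - {id: MZ1, kind: residue, chain: A, residues: [7, 8], flanking: [A1, A2]}
      - {id: termA, kind: residue, chain: A, residues: [1], flanking: [null, A1], permanent: true}
    torsions:
      - {id: phi1, chain: A, axis: [[9, C4], [9, C5], [9, C5M], [9, O5]], moving: [[9, O5], [9, HO5]]}
    toggles:              # optional; defaults to MZs (chain order) then torsions
      - {label: phi1, torsions: [phi1]}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .decomposition import (
    Chain,
    Decomposition,
    MoltenZone,
    Segment,
    StructureIndex,
    Toggle,
    TorsionDOF,
)
from .sampler import SamplerConfig

__all__ = [
    "decomposition_from_dict",
    "decomposition_to_dict",
    "load_decomposition",
    "save_decomposition",
    "load_sampler_config",
]


def decomposition_from_dict(data: dict) -> Decomposition:
    chains = tuple(
        Chain(str(cid), tuple(range(int(lo), int(hi) + 1)))
        for cid, (lo, hi) in data["chains"].items()
    )
    segments = tuple(
        Segment(s["id"], str(s["chain"]), int(s["range"][0]), int(s["range"][1]))
        for s in data.get("segments", [])
    )
    mzs = []
    for m in data.get("molten_zones", []):
        kind = m.get("kind", "residue")
        flanking = tuple(m.get("flanking", (None, None)))
        mzs.append(
            MoltenZone(
                m["id"],
                kind,
                str(m["chain"]),
                residues=tuple(int(r) for r in m.get("residues", ())),
                atoms=tuple((int(r), str(a)) for r, a in m.get("atoms", ())),
                flanking=flanking,
                permanent=bool(m.get("permanent", False)),
            )
        )
    torsions = tuple(
        TorsionDOF(
            t["id"],
            str(t["chain"]),
            axis_atoms=tuple((int(r), str(a)) for r, a in t["axis"]),
            moving=tuple((int(r), str(a)) for r, a in t["moving"]),
        )
        for t in data.get("torsions", [])
    )
    toggles = None
    if "toggles" in data:
        toggles = tuple(
            Toggle(
                g["label"],
                mz_ids=tuple(g.get("molten_zones", ())),
                torsion_ids=tuple(g.get("torsions", ())),
            )
            for g in data["toggles"]
        )
    return Decomposition(
        structure=StructureIndex(chains=chains),
        segments=segments,
        molten_zones=tuple(mzs),
        torsions=torsions,
        toggles=toggles,
    )


def decomposition_to_dict(d: Decomposition) -> dict:
    data: dict = {
        "chains": {str(c.id): [int(c.head), int(c.tail)] for c in d.structure.chains},
        "segments": [
            {"id": str(s.id), "chain": str(s.chain), "range": [int(s.head), int(s.tail)]}
            for s in d.segments
        ],
        "molten_zones": [],
        "torsions": [],
    }
    for m in d.molten_zones:
        entry: dict = {
            "id": str(m.id),
            "kind": str(m.kind),
            "chain": str(m.chain),
            "flanking": [None if f is None else str(f) for f in m.flanking],
        }
        if m.residues:
            entry["residues"] = [int(r) for r in m.residues]
        if m.atoms:
            entry["atoms"] = [[int(r), str(a)] for r, a in m.atoms]
        if m.permanent:
            entry["permanent"] = True
        data["molten_zones"].append(entry)
    for t in d.torsions:
        data["torsions"].append(
            {
                "id": str(t.id),
                "chain": str(t.chain),
                "axis": [[int(r), str(a)] for r, a in t.axis_atoms],
                "moving": [[int(r), str(a)] for r, a in t.moving],
            }
        )
    if d.toggles is not None:
        data["toggles"] = [
            {
                "label": str(g.label),
                **({"molten_zones": [str(x) for x in g.mz_ids]} if g.mz_ids else {}),
                **({"torsions": [str(x) for x in g.torsion_ids]} if g.torsion_ids else {}),
            }
            for g in d.toggles
        ]
    return data


def load_decomposition(path: str | Path) -> Decomposition:
    with open(path) as fh:
        return decomposition_from_dict(yaml.safe_load(fh))


def save_decomposition(d: Decomposition, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(decomposition_to_dict(d), fh, sort_keys=False)


def load_sampler_config(path: str | Path) -> SamplerConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "temperatures" in data:
        data["temperatures"] = tuple(float(t) for t in data["temperatures"])
    return SamplerConfig(**data)
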