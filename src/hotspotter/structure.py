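"""Complex structures: PDB reading, protomer partitioning, interface detection
and residue-residue contact queries.

A complex is modelled as two *protomers* (chain groups) of `ResidueRecord`s.
All distance-based machinery operates on heavy atoms only (hydrogens are
dropped at parse time; most crystal structures lack them anyway) and is backed
by a single KD-tree over the whole complex.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .properties import AA3_TO_1, NONSTANDARD_ALIASES

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class ChainSpecError(ValueError):
    """Malformed protomer chain-group specification."""


class MissingChainError(ValueError):
    """A chain named in the protomer spec is absent from the structure."""


class EmptyProtomerError(ValueError):
    """A protomer contains no standard amino-acid residues."""


class ResidueNotInComplexError(ValueError):
    """Residue passed to a contact query does not belong to the complex."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class ResidueRecord:
    chain_id: str
    protomer_id: str  # "A" or "B"
    seq_number: int
    icode: str
    aa_type: str  # one-letter code, standard 20
    atoms: List[Atom]
    is_interface: bool = False
    index: int = -1  # position within the complex residue list
    chain_pos: int = -1  # ordinal within its chain (for i+-1 exclusion)
    _heavy: Optional[np.ndarray] = field(default=None, repr=False)

    def heavy_coords(self) -> np.ndarray:
        if self._heavy is None:
            coords = [a.coords for a in self.atoms if a.is_heavy]
            self._heavy = np.asarray(coords, dtype=float).reshape(-1, 3)
        return self._heavy

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.icode)


class ComplexModel:
    """Two interacting protomers of a protein-protein complex."""

    def __init__(self, protomer_a: Sequence[ResidueRecord],
                 protomer_b: Sequence[ResidueRecord], source_id: str = "") -> None:
        if not protomer_a or not protomer_b:
            raise EmptyProtomerError(
                f"both protomers must contain standard residues (got "
                f"{len(protomer_a)} / {len(protomer_b)}) in {source_id!r}")
        chains_a = {r.chain_id for r in protomer_a}
        chains_b = {r.chain_id for r in protomer_b}
        if chains_a & chains_b:
            raise ChainSpecError(f"protomer chain sets overlap: {chains_a & chains_b}")
        self.source_id = source_id
        self.residues: List[ResidueRecord] = list(protomer_a) + list(protomer_b)
        for idx, res in enumerate(self.residues):
            res.index = idx
        self._n_a = len(protomer_a)
        self._assign_chain_positions()
        self._tree: Optional[cKDTree] = None
        self._atom_res: Optional[np.ndarray] = None

    def _assign_chain_positions(self) -> None:
        counters: dict = {}
        for res in self.residues:
            pos = counters.get(res.chain_id, 0)
            res.chain_pos = pos
            counters[res.chain_id] = pos + 1

    @property
    def protomer_a(self) -> List[ResidueRecord]:
        return self.residues[: self._n_a]

    @property
    def protomer_b(self) -> List[ResidueRecord]:
        return self.residues[self._n_a:]

    def protomer(self, protomer_id: str) -> List[ResidueRecord]:
        return self.protomer_a if protomer_id == "A" else self.protomer_b

    def interface_residues(self, protomer_id: Optional[str] = None) -> List[ResidueRecord]:
        pool = self.residues if protomer_id is None else self.protomer(protomer_id)
        return [r for r in pool if r.is_interface]

    # -- spatial index -----------------------------------------------------

    def _ensure_index(self) -> None:
        if self._tree is not None:
            return
        coords = []
        owner = []
        for res in self.residues:
            xyz = res.heavy_coords()
            coords.append(xyz)
            owner.append(np.full(len(xyz), res.index))
        all_xyz = np.vstack(coords)
        self._atom_res = np.concatenate(owner)
        self._tree = cKDTree(all_xyz)

    def invalidate_index(self) -> None:
        """Drop cached KD-tree and per-residue coordinates (after moving atoms)."""
        self._tree = None
        self._atom_res = None
        for res in self.residues:
            res._heavy = None

    def partners(self, residue: ResidueRecord, cutoff: float,
                 scope: str = "both") -> List[ResidueRecord]:
        """Residues with any heavy atom within `cutoff` of `residue`.

        Excludes the residue itself and its i+-1 sequence neighbors within the
        same chain; `scope` restricts partners to the same protomer,
        the opposite protomer, or both.
        """
        if scope not in ("same", "opposite", "both"):
            raise ValueError(f"scope must be same|opposite|both, got {scope!r}")
        if residue.index < 0 or residue.index >= len(self.residues) \
                or self.residues[residue.index] is not residue:
            raise ResidueNotInComplexError(
                f"residue {residue.key()} does not belong to complex {self.source_id!r}")
        self._ensure_index()
        hits = self._tree.query_ball_point(residue.heavy_coords(), r=cutoff)
        res_ids = {int(self._atom_res[i]) for lst in hits for i in lst}
        res_ids.discard(residue.index)
        out = []
        same_prot = residue.index < self._n_a
        for idx in sorted(res_ids):
            other = self.residues[idx]
            if other.chain_id == residue.chain_id and \
                    abs(other.chain_pos - residue.chain_pos) == 1:
                continue
            other_same = idx < self._n_a
            if scope == "same" and other_same != same_prot:
                continue
            if scope == "opposite" and other_same == same_prot:
                continue
            out.append(other)
        return out

    def min_distance(self, r1: ResidueRecord, r2: ResidueRecord) -> float:
        a, b = r1.heavy_coords(), r2.heavy_coords()
        d = a[:, None, :] - b[None, :, :]
        return float(np.sqrt((d ** 2).sum(axis=2)).min())

    # -- serialization -----------------------------------------------------

    def to_pdb(self) -> str:
        """Render the complex back to PDB text (heavy atoms, single model)."""
        lines = []
        serial = 1
        last_chain = None
        from .properties import AA1_TO_3
        for res in self.residues:
            if last_chain is not None and res.chain_id != last_chain:
                lines.append("TER")
            last_chain = res.chain_id
            resname = AA1_TO_3[res.aa_type]
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {res.chain_id:1s}"
                    f"{res.seq_number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}")
                serial += 1
        lines.append("TER")
        lines.append("END")
        return "\n".join(lines) + "\n"


def parse_protomer_spec(spec: str) -> Tuple[List[str], List[str]]:
    """Parse a chain-group spec like "A:B", "AB:CD" or "A,B:C" into two groups."""
    parts = spec.split(":")
    if len(parts) != 2:
        raise ChainSpecError(f"protomer spec must have exactly one ':', got {spec!r}")
    groups = []
    for part in parts:
        ids = part.split(",") if "," in part else list(part)
        ids = [c for c in ids if c]
        if not ids:
            raise ChainSpecError(f"empty chain group in spec {spec!r}")
        groups.append(ids)
    if set(groups[0]) & set(groups[1]):
        raise ChainSpecError(f"chain groups overlap in spec {spec!r}")
    return groups[0], groups[1]


def _resolve_altlocs(residue: gemmi.Residue) -> List[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties by altloc order."""
    by_name: dict = {}
    for at in residue:
        key = at.name
        prev = by_name.get(key)
        if prev is None:
            by_name[key] = at
            continue
        alt_prev = prev.altloc or "~"  # blank altloc sorts after letters? no:
        # blank altloc means the only conformer; prefer higher occupancy, then
        # lexicographically smaller altloc identifier.
        alt_new = at.altloc or "~"
        if (at.occ, _neg_ord(alt_new)) > (prev.occ, _neg_ord(alt_prev)):
            by_name[key] = at
    return list(by_name.values())


def _neg_ord(c: str) -> int:
    return -ord(c[0])


def read_complex(pdb_source, protomer_spec: str, source_id: str = "") -> ComplexModel:
    """Read a PDB file/stream/text and partition chains into two protomers.

    Model 1 is used for multi-model files; waters and unrecognized hetero
    groups are excluded; alternate locations resolve to the highest-occupancy
    conformer; hydrogens are dropped.
    """
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
    else:
        text = str(pdb_source)
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise ValueError("PDB source contains no models")
    model = structure[0]
    group_a, group_b = parse_protomer_spec(protomer_spec)
    available = [chain.name for chain in model]
    for cid in group_a + group_b:
        if cid not in available:
            raise MissingChainError(
                f"chain {cid!r} not found; available chains: {sorted(set(available))}")

    def collect(group: List[str], protomer_id: str) -> List[ResidueRecord]:
        records = []
        for cid in group:
            chain = model[cid]
            for res in chain:
                name = res.name.strip().upper()
                if name in _WATER_NAMES:
                    continue
                name = NONSTANDARD_ALIASES.get(name, name)
                aa1 = AA3_TO_1.get(name)
                if aa1 is None:
                    logger.warning("skipping non-standard residue %s %s%d in %s",
                                   res.name, cid, res.seqid.num, source_id)
                    continue
                atoms = []
                for at in _resolve_altlocs(res):
                    if at.element.is_hydrogen:
                        continue
                    atoms.append(Atom(
                        name=at.name,
                        element=at.element.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                    ))
                if not atoms:
                    continue
                records.append(ResidueRecord(
                    chain_id=cid, protomer_id=protomer_id,
                    seq_number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    aa_type=aa1, atoms=atoms))
        return records

    res_a = collect(group_a, "A")
    res_b = collect(group_b, "B")
    if not res_a or not res_b:
        raise EmptyProtomerError(
            f"a protomer of {source_id or protomer_spec!r} has zero standard residues")
    return ComplexModel(res_a, res_b, source_id=source_id)


def detect_interface_residues(complex_model: ComplexModel,
                              cutoff: float = 4.5) -> ComplexModel:
    """Flag residues with any heavy atom within `cutoff` (inclusive) of the
    opposite protomer. Symmetric by construction; an empty interface is legal."""
    for res in complex_model.residues:
        res.is_interface = bool(complex_model.partners(res, cutoff, scope="opposite"))
    return complex_model


def contact_partners(complex_model: ComplexModel, residue: ResidueRecord,
                     cutoff: float, scope: str = "both") -> List[ResidueRecord]:
    """Module-level alias for :meth:`ComplexModel.partners`."""
    return complex_model.partners(residue, cutoff, scope)


def chain_sequence(complex_model: ComplexModel, chain_id: str) -> str:
    """One-letter sequence of a chain in residue order."""
    return "".join(r.aa_type for r in complex_model.residues if r.chain_id == chain_id)
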