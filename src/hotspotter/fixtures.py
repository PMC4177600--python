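"""Deterministic synthetic two-chain complexes and alignments for testing.

The generator emits small poly-alanine-like scaffolds (PDB text) whose two
chains face each other across the x = 0 plane, with *planted features* laid
out in separate y-bands along the interface:

* strong sites - a His donor (chain A) hydrogen-bonded to an Asp acceptor
  and a Ser helper (chain B), surrounded by Trp/Phe packers; sites sit in
  adjacent bands so their residues cluster within 7 A. The His residues are
  the planted "strong" residues: by construction their energy, conservation,
  mass-index and clustering subscores all clear the published thresholds.
* salt_bridge - a Lys/Asp pair with NZ-carboxylate contacts at ~4 A
  (electrostatics without a hydrogen bond).
* hbond_pair - a single Trp NE1 -> backbone-O bond, the only
  donor/acceptor geometry in its band.
* contact_pair - a plain Ala-Ala heavy-atom contact at 4.2 A (weak
  interface filler for calibration pools).
* exposed_loner - a barely-contacting, unconserved Gly planted to fail
  every subscore.

Alignments are ungapped FASTA rows: homologues mutate non-conserved columns
at a given noise rate; conserved columns are identical in every row. Side
chains are single-interaction-center pseudo-atoms carrying exactly the atom
names the energy kernels look for; the geometry is deliberately synthetic,
not a physical protein model. Fixed seed implies byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .properties import AA1_TO_3

BAND = 6.5  # y spacing between feature bands, A


class FixtureGeometryError(ValueError):
    """A planted feature's geometry failed its own realizability check."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_strong_sites: int = 2
    with_salt_bridge: bool = True
    with_hbond_pair: bool = True
    n_contact_pairs: int = 2
    with_loner: bool = True
    jitter: float = 0.03  # uniform coordinate noise, A
    depth: int = 8        # alignment rows incl. query
    noise_rate: float = 0.3
    chain_separation: float = 16.0  # spine-to-spine distance (non-contacting)

    def __post_init__(self):
        if self.n_strong_sites < 0 or self.n_contact_pairs < 0:
            raise FixtureGeometryError("feature counts must be non-negative")
        if self.depth < 2:
            raise FixtureGeometryError("alignment depth must be >= 2")
        if not (0 <= self.noise_rate <= 1):
            raise FixtureGeometryError("noise_rate must be in [0, 1]")
        if self.jitter >= 0.15:
            raise FixtureGeometryError(
                "jitter >= 0.15 A can push planted contacts across cutoffs")


_Res = Tuple[str, List[Tuple[str, str, Tuple[float, float, float]]]]
# (one-letter aa, [(atom name, element, xyz)])


def _backbone(ca, side: int):
    """N/CA/C/O placed around a CA; `side` is -1 for chain A, +1 for chain B."""
    x, y, z = ca
    n = (x + 0.5 * side, y - 1.2, z + 0.8)  # leans away from the interface
    c = (x + 0.5 * side, y + 1.2, z + 0.8)
    o = (c[0] + 0.2 * side, c[1] + 0.2, c[2] + 1.1)
    return [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]


def _strong_site(y: float, k: int):
    """One strong site: returns (A residues, B residues, hbond atom pairs)."""
    a_res: List[_Res] = []
    b_res: List[_Res] = []
    zs = 2.4 if k % 2 == 0 else -2.4  # alternate packer z to avoid stacking
    # chain A: His donor, the planted strong residue
    his = _backbone((-4.0, y, 0.0), -1) + [
        ("CB", "C", (-3.6, y - 0.3, 0.9)),
        ("CG", "C", (-3.0, y - 0.6, 0.0)),
        ("CD2", "C", (-3.0, y + 0.6, 0.0)),
        ("ND1", "N", (-1.45, y - 1.1, 0.0)),
        ("NE2", "N", (-1.45, y + 1.1, 0.0)),
    ]
    a_res.append(("H", his))
    # chain B: Asp acceptor
    asp = _backbone((4.0, y - 1.1, 0.0), +1) + [
        ("CB", "C", (3.2, y - 1.4, 0.5)),
        ("CG", "C", (2.6, y - 1.1, 0.0)),
        ("OD1", "O", (1.45, y - 1.1, 0.0)),
        ("OD2", "O", (2.5, y - 2.0, -0.5)),
    ]
    b_res.append(("D", asp))
    # chain B: Ser helper (second acceptor/donor for the His NE2)
    ser = _backbone((4.0, y + 1.8, 0.5), +1) + [
        ("CB", "C", (2.8, y + 1.1, 0.6)),
        ("OG", "O", (1.45, y + 1.1, 0.0)),
    ]
    b_res.append(("S", ser))
    # packers: Phe on A below the site, Trp on B above it
    phe = _backbone((-2.5, y - 4.8, 3.0), -1) + [
        ("CB", "C", (0.0, y - 3.6, zs)),
    ]
    a_res.append(("F", phe))
    trp = _backbone((2.5, y + 4.8, 3.0), +1) + [
        ("CB", "C", (0.0, y + 3.6, zs)),
    ]
    b_res.append(("W", trp))
    hbonds = [(("A", "ND1"), ("B", "OD1")), (("A", "NE2"), ("B", "OG"))]
    return a_res, b_res, hbonds


def _salt_bridge(y: float):
    lys = _backbone((-4.0, y, 0.0), -1) + [
        ("CB", "C", (-3.4, y, 0.6)),
        ("CE", "C", (-3.0, y, 0.0)),
        ("NZ", "N", (-1.8, y, 0.0)),
    ]
    asp = _backbone((4.0, y, 0.0), +1) + [
        ("CB", "C", (3.2, y, 0.5)),
        ("CG", "C", (2.6, y, 0.0)),
        ("OD1", "O", (2.2, y, 0.0)),
        ("OD2", "O", (2.9, y + 1.1, -0.8)),
    ]
    return ("K", lys), ("D", asp)


def _hbond_pair(y: float):
    trp = _backbone((-4.0, y, 0.0), -1) + [
        ("CB", "C", (-3.6, y, 0.8)),
        ("CD1", "C", (-3.0, y, 0.0)),
        ("NE1", "N", (-1.45, y, 0.0)),
    ]
    # Ala whose backbone carbonyl O points into the interface
    ala = [
        ("N", "N", (3.0, y - 2.0, -1.2)),
        ("CA", "C", (3.0, y - 0.8, -1.8)),
        ("C", "C", (2.0, y, -1.3)),
        ("O", "O", (1.45, y, 0.0)),
        ("CB", "C", (4.0, y - 0.5, -2.5)),
    ]
    return ("W", trp), ("A", ala)


def _contact_pair(y: float):
    a = _backbone((-3.5, y, 0.6), -1) + [("CB", "C", (-2.1, y, 0.0))]
    b = _backbone((3.5, y, 0.6), +1) + [("CB", "C", (2.1, y, 0.0))]
    return ("A", a), ("A", b)


def _loner(y: float):
    gly = [
        ("N", "N", (-2.8, y - 1.1, 0.6)),
        ("CA", "C", (-2.1, y, 0.0)),
        ("C", "C", (-1.6, y + 1.2, 0.6)),
        ("O", "O", (-1.4, y + 1.4, 1.7)),
    ]
    ala = _backbone((3.5, y, 0.6), +1) + [("CB", "C", (2.1, y, 0.0))]
    return ("G", gly), ("A", ala)


def _spine(y: float, side: int, half_gap: float):
    x = side * half_gap
    return ("A", _backbone((x, y, 0.0), side)
            + [("CB", "C", (x + 0.8 * side, y, -0.5))])


def make_complex(spec: FixtureSpec) -> Tuple[str, dict]:
    """Build the fixture complex; returns (PDB text, ground-truth manifest)."""
    rng = np.random.default_rng(spec.seed)
    half_gap = spec.chain_separation / 2.0

    feats_a: List[Tuple[str, _Res]] = []  # (feature tag, residue)
    feats_b: List[Tuple[str, _Res]] = []
    hbond_atoms: List[Tuple[Tuple[str, str], Tuple[str, str]]] = []

    for k in range(spec.n_strong_sites):
        y = BAND * k
        a_res, b_res, hb = _strong_site(y, k)
        feats_a.append((f"strong:{k}", a_res[0]))
        feats_a.append((f"packer:{k}", a_res[1]))
        feats_b.append((f"acceptor:{k}", b_res[0]))
        feats_b.append((f"helper:{k}", b_res[1]))
        feats_b.append((f"packer:{k}", b_res[2]))
        hbond_atoms.extend(hb)

    next_band = -1
    if spec.with_salt_bridge:
        a, b = _salt_bridge(BAND * next_band)
        feats_a.append(("salt_bridge", a))
        feats_b.append(("salt_bridge", b))
        next_band -= 1
    if spec.with_hbond_pair:
        a, b = _hbond_pair(BAND * next_band)
        feats_a.append(("hbond_pair", a))
        feats_b.append(("hbond_pair", b))
        hbond_atoms.append((("A", "NE1"), ("B", "O")))
        next_band -= 1
    for _ in range(spec.n_contact_pairs):
        a, b = _contact_pair(BAND * next_band)
        feats_a.append(("contact_pair", a))
        feats_b.append(("contact_pair", b))
        next_band -= 1
    if spec.with_loner:
        a, b = _loner(BAND * next_band)
        feats_a.append(("exposed_loner", a))
        feats_b.append(("loner_partner", b))
        next_band -= 1

    # interleave a far-spine Ala before every feature residue so planted
    # residues are never sequence-adjacent (i+-1 contacts are excluded by
    # the contact machinery)
    def interleave(feats, side):
        chain: List[Tuple[str, _Res]] = []
        y_top = BAND * (spec.n_strong_sites + 1)
        for i, item in enumerate(feats):
            chain.append(("spine", _spine(y_top + BAND * i, side, half_gap)))
            chain.append(item)
        chain.append(("spine", _spine(y_top + BAND * len(feats), side, half_gap)))
        return chain

    chain_a = interleave(feats_a, -1)
    chain_b = interleave(feats_b, +1)

    manifest: dict = {
        "seed": spec.seed,
        "strong": [], "loner": None, "salt_bridge": [], "hbond_pairs": [],
        "support": [], "conserved_positions": {"A": [], "B": []},
        "chains": {},
    }
    atom_xyz: Dict[Tuple[str, int, str], Tuple[float, float, float]] = {}

    lines: List[str] = []
    serial = 1
    for chain_id, chain in (("A", chain_a), ("B", chain_b)):
        seq = []
        for pos, (tag, (aa, atoms)) in enumerate(chain, start=1):
            seq.append(aa)
            entry = {"chain": chain_id, "resnum": pos, "aa": aa}
            if tag.startswith("strong"):
                manifest["strong"].append(entry)
            elif tag == "exposed_loner":
                manifest["loner"] = entry
            elif tag == "salt_bridge":
                manifest["salt_bridge"].append(entry)
            elif tag.startswith(("acceptor", "helper", "packer")):
                manifest["support"].append({**entry, "role": tag})
            if tag.startswith(("strong", "acceptor", "helper")):
                manifest["conserved_positions"][chain_id].append(pos - 1)
            resname = AA1_TO_3[aa]
            for name, element, xyz in atoms:
                jit = rng.uniform(-spec.jitter, spec.jitter, size=3)
                x, y, z = (np.asarray(xyz) + jit)
                atom_xyz[(chain_id, pos, name)] = (x, y, z)
                pdb_name = name if len(name) >= 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {resname:<3s} "
                    f"{chain_id:1s}{pos:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}")
                serial += 1
        manifest["chains"][chain_id] = "".join(seq)
        lines.append("TER")
    lines.append("END")

    # realizability check: every planted hydrogen bond must satisfy the
    # geometric detection window after jitter
    def _locate(chain_id, name):
        hits = [(key, xyz) for key, xyz in atom_xyz.items()
                if key[0] == chain_id and key[2] == name]
        return hits

    for (ch_d, dname), (ch_a, aname) in hbond_atoms:
        best = None
        for dkey, dxyz in _locate(ch_d, dname):
            for akey, axyz in _locate(ch_a, aname):
                d = float(np.linalg.norm(np.subtract(dxyz, axyz)))
                if best is None or d < best[0]:
                    best = (d, dkey, akey)
        if best is None or not (2.5 <= best[0] <= 3.5):
            raise FixtureGeometryError(
                f"planted hydrogen bond {dname}->{aname} unrealizable "
                f"(closest distance {best[0] if best else 'n/a'})")
        manifest["hbond_pairs"].append({
            "donor": list(best[1]), "acceptor": list(best[2]),
            "distance": round(best[0], 3)})

    return "\n".join(lines) + "\n", manifest


def make_alignment(chain_sequence: str, conserved_positions: Sequence[int],
                   depth: int, noise_rate: float, seed: int
                   ) -> Tuple[str, dict]:
    """Ungapped FASTA alignment: a query plus `depth - 1` homologues that
    mutate non-conserved columns at `noise_rate`; returns (text, manifest
    with pairwise identities to the query)."""
    if depth < 2:
        raise FixtureGeometryError("alignment depth must be >= 2")
    bad = [p for p in conserved_positions if not 0 <= p < len(chain_sequence)]
    if bad:
        raise FixtureGeometryError(f"conserved positions out of range: {bad}")
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    conserved = set(conserved_positions)
    rows = [("query", chain_sequence)]
    identities = []
    for h in range(1, depth):
        seq = []
        for i, aa in enumerate(chain_sequence):
            if i in conserved or rng.random() >= noise_rate:
                seq.append(aa)
            else:
                choices = [c for c in alphabet if c != aa]
                seq.append(choices[rng.integers(len(choices))])
        hom = "".join(seq)
        rows.append((f"hom{h}", hom))
        identities.append(sum(a == b for a, b in zip(chain_sequence, hom))
                          / len(chain_sequence))
    text = "".join(f">{rid}\n{seq}\n" for rid, seq in rows)
    return text, {"identities_to_query": identities, "seed": seed}


def make_case(spec: Optional[FixtureSpec] = None, seed: Optional[int] = None
              ) -> dict:
    """Full fixture bundle: PDB text, per-chain alignments, and manifest."""
    if spec is None:
        spec = FixtureSpec(seed=seed or 0)
    elif seed is not None:
        raise ValueError("pass either spec or seed, not both")
    pdb_text, manifest = make_complex(spec)
    alignments = {}
    for chain_id, seq in manifest["chains"].items():
        text, aln_manifest = make_alignment(
            seq, manifest["conserved_positions"][chain_id],
            depth=spec.depth, noise_rate=spec.noise_rate,
            seed=spec.seed * 2 + (0 if chain_id == "A" else 1))
        alignments[chain_id] = text
        manifest.setdefault("alignment_manifests", {})[chain_id] = aln_manifest
    return {"pdb": pdb_text, "alignments": alignments, "manifest": manifest,
            "protomer_spec": "A:B"}


def manifest_to_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=1, sort_keys=True)
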