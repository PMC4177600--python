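"""Per-residue cross-interface interaction energies.

Three non-covalent components are evaluated over heavy-atom pairs spanning the
interface and attributed to *both* residues of each pair (the per-residue
decomposition everything downstream scores):

* Van der Waals: 12-6 Lennard-Jones on united heavy atoms with
  Lorentz-Berthelot combining; the pair minimum sits at the sum of the atomic
  radii. Pairs participating in a detected hydrogen bond are excluded.
* Electrostatics: Coulomb term 332*qi*qj / (eps(r)*r) with a
  distance-dependent dielectric eps(r) = 4r and formal side-chain charges
  (Asp/Glu -0.5 per carboxylate oxygen, Lys NZ +1, Arg +0.5 per NH1/NH2;
  His neutral).
* Hydrogen bonds: geometric detection on heavy atoms - donor-acceptor
  distance within [2.5, 3.5] A and antecedent-donor-acceptor angle >= 90
  degrees - each bond contributing a fixed -1.0 kcal/mol to both partners.

These forms are deliberately simple and hydrogen-free; all constants live in
`AtomParameters` / `ParameterSet`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from .properties import aa_properties, UnknownResidueError
from .structure import ComplexModel, ResidueRecord

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class EnergyComponents:
    """Summed cross-protomer energy contributions of one residue (kcal/mol)."""

    vdw: float = 0.0
    elec: float = 0.0
    hbond: float = 0.0


@dataclass(frozen=True)
class EnergyWeights:
    """Component weights of the total per-residue energy."""

    w_vw: float = 1.4
    w_es: float = 1.0
    w_hb: float = 9.0


def _default_lj_radius() -> Dict[str, float]:
    return {"C": 1.95, "N": 1.85, "O": 1.75, "S": 2.00}


def _default_lj_eps() -> Dict[str, float]:
    return {"C": 0.12, "N": 0.16, "O": 0.20, "S": 0.25}


def _default_charges() -> Dict[str, Dict[str, float]]:
    return {
        "D": {"OD1": -0.5, "OD2": -0.5},
        "E": {"OE1": -0.5, "OE2": -0.5},
        "K": {"NZ": 1.0},
        "R": {"NH1": 0.5, "NH2": 0.5},
    }


def _default_donors() -> Dict[str, Dict[str, str]]:
    # residue -> {donor atom: antecedent atom}
    common = {"N": "CA"}
    table = {aa: dict(common) for aa in "ACDEFGHIKLMNQRSTVWY"}
    table["P"] = {}  # proline backbone N has no H
    table["S"]["OG"] = "CB"
    table["T"]["OG1"] = "CB"
    table["Y"]["OH"] = "CZ"
    table["N"]["ND2"] = "CG"
    table["Q"]["NE2"] = "CD"
    table["K"]["NZ"] = "CE"
    table["R"].update({"NE": "CD", "NH1": "CZ", "NH2": "CZ"})
    table["W"]["NE1"] = "CD1"
    table["H"].update({"ND1": "CG", "NE2": "CD2"})
    return table


def _default_acceptors() -> Dict[str, Tuple[str, ...]]:
    base = ("O",)  # backbone carbonyl
    table = {aa: base for aa in "ACDEFGHIKLMNPQRSTVWY"}
    table["D"] = base + ("OD1", "OD2")
    table["E"] = base + ("OE1", "OE2")
    table["N"] = base + ("OD1",)
    table["Q"] = base + ("OE1",)
    table["S"] = base + ("OG",)
    table["T"] = base + ("OG1",)
    table["Y"] = base + ("OH",)
    table["H"] = base + ("ND1", "NE2")
    return table


@dataclass
class AtomParameters:
    """Lennard-Jones radii/well depths, formal charges, donor/acceptor tables."""

    lj_radius: Dict[str, float] = field(default_factory=_default_lj_radius)
    lj_eps: Dict[str, float] = field(default_factory=_default_lj_eps)
    charges: Dict[str, Dict[str, float]] = field(default_factory=_default_charges)
    donors: Dict[str, Dict[str, str]] = field(default_factory=_default_donors)
    acceptors: Dict[str, Tuple[str, ...]] = field(default_factory=_default_acceptors)
    hbond_energy_kcal: float = -1.0
    hbond_dist_min: float = 2.5
    hbond_dist_max: float = 3.5
    hbond_angle_min_deg: float = 90.0

    def radius(self, element: str) -> float:
        return self.lj_radius.get(element.upper(), self.lj_radius["C"])

    def eps(self, element: str) -> float:
        return self.lj_eps.get(element.upper(), self.lj_eps["C"])


@dataclass(frozen=True)
class HydrogenBond:
    donor_res: int  # residue index in the complex
    acceptor_res: int
    donor_atom: str
    acceptor_atom: str


AtomId = Tuple[int, str]  # (residue index, atom name)


def hydrogen_bonds(complex_model: ComplexModel,
                   params: Optional[AtomParameters] = None) -> List[HydrogenBond]:
    """Detect all cross-protomer hydrogen bonds by heavy-atom geometry.

    Donor-acceptor distance in [dist_min, dist_max] and
    angle(antecedent, donor, acceptor) >= angle_min; a donor with a missing
    antecedent atom is accepted on distance alone.
    """
    params = params or AtomParameters()
    bonds: List[HydrogenBond] = []
    seen: Set[FrozenSet[AtomId]] = set()
    side_a = complex_model.protomer_a
    side_b = complex_model.protomer_b

    def scan(donor_side, acceptor_side):
        for dres in donor_side:
            dtable = params.donors.get(dres.aa_type, {})
            for dname, antecedent in dtable.items():
                datom = dres.atom(dname)
                if datom is None:
                    continue
                ant = dres.atom(antecedent)
                for ares in acceptor_side:
                    for aname in params.acceptors.get(ares.aa_type, ()):
                        aatom = ares.atom(aname)
                        if aatom is None:
                            continue
                        d = float(np.linalg.norm(datom.coords - aatom.coords))
                        if not (params.hbond_dist_min <= d <= params.hbond_dist_max):
                            continue
                        if ant is not None:
                            v1 = ant.coords - datom.coords
                            v2 = aatom.coords - datom.coords
                            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                            if denom > 0:
                                cosang = float(np.dot(v1, v2) / denom)
                                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                                if angle < params.hbond_angle_min_deg:
                                    continue
                        # one physical bond per atom pair, whichever
                        # orientation detected it first
                        pair = frozenset({(dres.index, dname),
                                          (ares.index, aname)})
                        if pair in seen:
                            continue
                        seen.add(pair)
                        bonds.append(HydrogenBond(dres.index, ares.index,
                                                  dname, aname))
        return

    scan(side_a, side_b)
    scan(side_b, side_a)
    return bonds


def hbond_excluded_pairs(bonds: List[HydrogenBond]) -> Set[FrozenSet[AtomId]]:
    """Atom pairs engaged in a hydrogen bond, to exclude from the LJ sum."""
    return {frozenset({(b.donor_res, b.donor_atom), (b.acceptor_res, b.acceptor_atom)})
            for b in bonds}


def _opposite_residues(complex_model: ComplexModel,
                       residue: ResidueRecord) -> List[ResidueRecord]:
    in_a = residue.index < len(complex_model.protomer_a)
    return complex_model.protomer_b if in_a else complex_model.protomer_a


def vdw_energy(residue: ResidueRecord, complex_model: ComplexModel,
               params: Optional[AtomParameters] = None, cutoff: float = 8.0,
               excluded: Optional[Set[FrozenSet[AtomId]]] = None) -> float:
    """12-6 Lennard-Jones sum over cross-protomer heavy-atom pairs (kcal/mol)."""
    params = params or AtomParameters()
    excluded = excluded if excluded is not None else set()
    total = 0.0
    for other in _opposite_residues(complex_model, residue):
        for a1 in residue.atoms:
            for a2 in other.atoms:
                pair = frozenset({(residue.index, a1.name), (other.index, a2.name)})
                if pair in excluded:
                    continue
                r = float(np.linalg.norm(a1.coords - a2.coords))
                if r > cutoff or r <= 0:
                    continue
                rmin = params.radius(a1.element) + params.radius(a2.element)
                eps = math.sqrt(params.eps(a1.element) * params.eps(a2.element))
                ratio6 = (rmin / r) ** 6
                total += eps * (ratio6 * ratio6 - 2.0 * ratio6)
    return total


def electrostatic_energy(residue: ResidueRecord, complex_model: ComplexModel,
                         params: Optional[AtomParameters] = None,
                         cutoff: float = 10.0) -> float:
    """Coulomb sum over cross-protomer formally charged atom pairs with a
    distance-dependent dielectric eps(r) = 4r (kcal/mol)."""
    params = params or AtomParameters()
    own = params.charges.get(residue.aa_type, {})
    if not own:
        return 0.0
    total = 0.0
    for other in _opposite_residues(complex_model, residue):
        partner = params.charges.get(other.aa_type, {})
        if not partner:
            continue
        for name_i, qi in own.items():
            ai = residue.atom(name_i)
            if ai is None:
                continue
            for name_j, qj in partner.items():
                aj = other.atom(name_j)
                if aj is None:
                    continue
                r = float(np.linalg.norm(ai.coords - aj.coords))
                if r > cutoff or r <= 0:
                    continue
                total += COULOMB_CONSTANT * qi * qj / (4.0 * r * r)
    return total


def hbond_energy(residue: ResidueRecord, complex_model: ComplexModel,
                 params: Optional[AtomParameters] = None,
                 bonds: Optional[List[HydrogenBond]] = None) -> float:
    """Fixed per-bond energy summed over the residue's cross-protomer hydrogen
    bonds; each detected bond is attributed to both partner residues."""
    params = params or AtomParameters()
    if bonds is None:
        bonds = hydrogen_bonds(complex_model, params)
    n = sum(1 for b in bonds if residue.index in (b.donor_res, b.acceptor_res))
    return n * params.hbond_energy_kcal


def interface_energy_components(
        complex_model: ComplexModel,
        params: Optional[AtomParameters] = None,
        vdw_cutoff: float = 8.0,
        elec_cutoff: float = 10.0) -> Dict[int, EnergyComponents]:
    """Energy components for every interface residue, keyed by residue index."""
    params = params or AtomParameters()
    bonds = hydrogen_bonds(complex_model, params)
    excluded = hbond_excluded_pairs(bonds)
    out: Dict[int, EnergyComponents] = {}
    for res in complex_model.residues:
        if not res.is_interface:
            continue
        out[res.index] = EnergyComponents(
            vdw=vdw_energy(res, complex_model, params, vdw_cutoff, excluded),
            elec=electrostatic_energy(res, complex_model, params, elec_cutoff),
            hbond=hbond_energy(res, complex_model, params, bonds),
        )
    return out


def weighted_residue_energy(components: EnergyComponents,
                            weights: EnergyWeights) -> float:
    """Weighted total energy e_i = w_VW*VW + w_ES*ES + w_HB*HB (kcal/mol)."""
    return (weights.w_vw * components.vdw
            + weights.w_es * components.elec
            + weights.w_hb * components.hbond)


def volume_normalized_energy(e_i: float, aa_type: str) -> float:
    """Energy per residue volume, ne_i = e_i / V_i (kcal/(mol*A^3))."""
    volume = aa_properties().get_volume(aa_type)
    return e_i / volume


def energy_subscore(ne_i: float, ne_max: float) -> float:
    """Map the volume-normalized energy onto [0, 1].

    Favorable (negative) energies map to |ne_i| / ne_max, clamped at 1;
    unfavorable (positive) energies map to 0.
    """
    if ne_max <= 0:
        raise ValueError(f"ne_max must be positive, got {ne_max}")
    if ne_i >= 0:
        return 0.0
    return min(abs(ne_i) / ne_max, 1.0)
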