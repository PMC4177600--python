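"""Packing-context subscores: mass index and spatial clustering.

The mass index of a residue is the summed residue mass of its contact
partners (closest heavy-atom distance <= 4.5 A by default, both protomers,
chain neighbors i+-1 excluded) - a proxy for how tightly packed and buried
the residue is. The spatial-clustering score counts, for residues already
supported by energy and conservation (average of the two subscores strictly
above 0.5), how many other such candidates lie within 7 A, capturing the
tendency of hotspots to aggregate into hot regions. Both are clamped to
[0, 1] by dataset-derived normalization constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Set

from .properties import AAPropertyTable, aa_properties
from .structure import ComplexModel, ResidueRecord


@dataclass(frozen=True)
class MassIndexResult:
    raw: float        # Da
    normalized: float  # [0, 1]
    n_partners: int = 0


@dataclass(frozen=True)
class ClusterResult:
    n_same: int
    n_cross: int
    raw: int
    normalized: float  # [0, 1]


def mass_index(residue: ResidueRecord, complex_model: ComplexModel,
               table: Optional[AAPropertyTable] = None,
               contact_cutoff: float = 4.5, mi_max: float = 1.0,
               include_self: bool = False) -> MassIndexResult:
    """Summed partner mass, normalized by `mi_max` and clamped at 1."""
    if mi_max <= 0:
        raise ValueError(f"mi_max must be positive, got {mi_max}")
    table = table or aa_properties()
    partners = complex_model.partners(residue, contact_cutoff, scope="both")
    raw = sum(table.get_mass(p.aa_type) for p in partners)
    if include_self:
        raw += table.get_mass(residue.aa_type)
    return MassIndexResult(raw=raw, normalized=min(raw / mi_max, 1.0),
                           n_partners=len(partners))


def cluster_score(residue: ResidueRecord, complex_model: ComplexModel,
                  candidate_set: Set[int], neighbor_cutoff: float = 7.0,
                  sc_max: float = 1.0) -> ClusterResult:
    """Count other candidate residues within `neighbor_cutoff` (closest heavy
    atoms), split by protomer; residues outside the candidate set score 0.

    `candidate_set` holds complex residue indices whose energy/conservation
    average exceeds the 0.5 gate (strict), computed upstream.
    """
    if sc_max <= 0:
        raise ValueError(f"sc_max must be positive, got {sc_max}")
    if residue.index not in candidate_set:
        return ClusterResult(n_same=0, n_cross=0, raw=0, normalized=0.0)
    neighbors = complex_model.partners(residue, neighbor_cutoff, scope="both")
    n_same = n_cross = 0
    in_a = residue.index < len(complex_model.protomer_a)
    for nb in neighbors:
        if nb.index not in candidate_set:
            continue
        if (nb.index < len(complex_model.protomer_a)) == in_a:
            n_same += 1
        else:
            n_cross += 1
    raw = n_same + n_cross
    return ClusterResult(n_same=n_same, n_cross=n_cross, raw=raw,
                         normalized=min(raw / sc_max, 1.0))
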