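"""Amino-acid property tables: residue masses and mean residue volumes.

Volumes are Zamyatnin mean residue volumes (A^3); masses are average residue
masses (Da, i.e. amino-acid mass minus one water). Both tables cover exactly
the 20 standard amino acids and are used to normalize per-residue interaction
energies (by volume) and to build the mass-index packing score (by mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


class UnknownResidueError(KeyError):
    """Raised when a residue code is not one of the 20 standard amino acids."""


AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_1 = {three: one for one, three in AA1_TO_3.items()}

#: fixed alias table for common modified residues (3-letter -> standard 3-letter)
NONSTANDARD_ALIASES = {"MSE": "MET"}

#: average residue mass, Da (monomer mass minus H2O)
RESIDUE_MASS_DA = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}

#: Zamyatnin mean residue volume, A^3
RESIDUE_VOLUME_A3 = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


@dataclass(frozen=True)
class AAPropertyTable:
    """Residue mass (Da) and mean residue volume (A^3) for the 20 standard AAs."""

    mass: Mapping[str, float]
    volume: Mapping[str, float]

    def get_mass(self, aa: str) -> float:
        try:
            return self.mass[aa]
        except KeyError:
            raise UnknownResidueError(f"no mass tabulated for residue code {aa!r}")

    def get_volume(self, aa: str) -> float:
        try:
            return self.volume[aa]
        except KeyError:
            raise UnknownResidueError(f"no volume tabulated for residue code {aa!r}")


_TABLE = AAPropertyTable(mass=dict(RESIDUE_MASS_DA), volume=dict(RESIDUE_VOLUME_A3))


def aa_properties() -> AAPropertyTable:
    """Return the packaged amino-acid property table."""
    return _TABLE
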