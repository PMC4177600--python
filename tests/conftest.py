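import numpy as np
import pytest

from hotspotter.conservation import read_alignment
from hotspotter.fixtures import FixtureSpec, make_case
from hotspotter.scoring import ParameterSet
from hotspotter.structure import Atom, ComplexModel, ResidueRecord, \
    detect_interface_residues, read_complex


def make_residue(chain, num, aa, atoms, protomer="A"):
    return ResidueRecord(
        chain_id=chain, protomer_id=protomer, seq_number=num, icode="",
        aa_type=aa,
        atoms=[Atom(name=n, element=e, coords=np.array(xyz, dtype=float))
               for n, e, xyz in atoms])


def toy_complex(a_specs, b_specs):
    """Build a ComplexModel from [(chain, num, aa, [(name, elem, xyz)])]."""
    res_a = [make_residue(c, n, aa, atoms, "A") for c, n, aa, atoms in a_specs]
    res_b = [make_residue(c, n, aa, atoms, "B") for c, n, aa, atoms in b_specs]
    return ComplexModel(res_a, res_b, source_id="toy")


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def fixture_case():
    return make_case(FixtureSpec(seed=0))


@pytest.fixture()
def fixture_complex(fixture_case):
    cm = read_complex(fixture_case["pdb"], "A:B", source_id="fix0")
    detect_interface_residues(cm)
    return cm


@pytest.fixture(scope="session")
def fixture_alignments(fixture_case):
    return {cid: read_alignment(text, "fasta", "query")
            for cid, text in fixture_case["alignments"].items()}


def brute_force_partners(cm, residue, cutoff, scope="both"):
    """All-pairs distance oracle for contact queries."""
    n_a = len(cm.protomer_a)
    out = []
    for other in cm.residues:
        if other is residue:
            continue
        if other.chain_id == residue.chain_id and \
                abs(other.chain_pos - residue.chain_pos) == 1:
            continue
        same = (other.index < n_a) == (residue.index < n_a)
        if scope == "same" and not same:
            continue
        if scope == "opposite" and same:
            continue
        d = min(np.linalg.norm(p - q)
                for p in residue.heavy_coords() for q in other.heavy_coords())
        if d <= cutoff:
            out.append(other)
    return out
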