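"""Evolutionary conservation from a pre-built multiple sequence alignment.

The pipeline mirrors how conservation is commonly derived for interface
scoring: homologues are de-redundified at 80 % pairwise identity (greedy, the
query always survives), then every query column is scored as the mean
substitution-matrix score over all unordered pairs of non-gap residues and
normalized by the matrix maximum (the Cys-Cys entry, 100) onto [0, 1].

Homologue search and alignment construction are external preprocessing; this
module only consumes an existing FASTA or Clustal alignment.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.")


class AlignmentError(ValueError):
    """Malformed alignment or missing query row."""


class ColumnDepthError(ValueError):
    """Fewer than two non-gap residues in a column; caller should fall back."""


class SequenceMismatchError(ValueError):
    """Structure chain sequence does not match the alignment's query row."""


@dataclass(frozen=True)
class Alignment:
    """Rows of (id, aligned sequence); `query_row` indexes the query chain."""

    ids: Tuple[str, ...]
    seqs: Tuple[str, ...]
    query_row: int

    def __post_init__(self):
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if not (0 <= self.query_row < len(self.seqs)):
            raise AlignmentError("query_row out of range")

    @property
    def n_rows(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def query_sequence(self) -> str:
        """The query row with gap characters stripped."""
        return "".join(c for c in self.seqs[self.query_row] if c not in GAP_CHARS)

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)


class SubstitutionMatrix:
    """Symmetric amino-acid pair scores on the 0-100 scale used here
    (the maximum, Cys-Cys, equals 100)."""

    def __init__(self, scores: np.ndarray, alphabet: str = AA_ALPHABET) -> None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (20, 20):
            raise ValueError(f"expected a 20x20 matrix, got {scores.shape}")
        if not np.allclose(scores, scores.T, atol=1e-9):
            raise ValueError("substitution matrix must be symmetric")
        self.alphabet = alphabet
        self._index = {aa: i for i, aa in enumerate(alphabet)}
        self.scores = scores

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"residue code not in matrix alphabet: {exc}")

    def max_score(self) -> float:
        return float(self.scores.max())


def johnson_overington_matrix() -> SubstitutionMatrix:
    """The Johnson & Overington (1993) structure-derived substitution matrix,
    rescaled so its maximum entry - the Cys-Cys diagonal - equals exactly 100.

    The log-odds form shipped with Biopython (maximum 1.61 at Cys-Cys) is
    multiplied by 100/1.61; the Cys-Cys anchor is asserted at load time.
    """
    raw = substitution_matrices.load("JOHNSON")
    alphabet = "".join(raw.alphabet)
    order = [alphabet.index(aa) for aa in AA_ALPHABET]
    arr = np.array(raw)[np.ix_(order, order)]
    cys = AA_ALPHABET.index("C")
    scaled = arr * (100.0 / arr[cys, cys])
    mat = SubstitutionMatrix(scaled)
    assert abs(mat.score("C", "C") - 100.0) < 1e-9
    assert mat.max_score() == mat.score("C", "C")
    return mat


def read_matrix_file(source) -> SubstitutionMatrix:
    """Read a whitespace-separated square or lower-triangular 20x20 matrix with
    a header row of one-letter codes."""
    text = source.read() if hasattr(source, "read") else str(source)
    lines = [ln.split() for ln in text.strip().splitlines() if ln.strip()
             and not ln.lstrip().startswith("#")]
    header = lines[0]
    if len(header) != 20:
        raise ValueError(f"matrix header must list 20 residue codes, got {len(header)}")
    idx = {aa: i for i, aa in enumerate(header)}
    full = np.full((20, 20), np.nan)
    for row in lines[1:]:
        aa, values = row[0], [float(v) for v in row[1:]]
        i = idx[aa]
        for j, v in enumerate(values):
            full[i, j] = v
            full[j, i] = v
    if np.isnan(full).any():
        raise ValueError("matrix file does not cover all residue pairs")
    order = [idx[aa] for aa in AA_ALPHABET]
    return SubstitutionMatrix(full[np.ix_(order, order)])


def read_alignment(source, fmt: str = "fasta", query_id: str = "") -> Alignment:
    """Read a FASTA or Clustal alignment and mark the query row."""
    if fmt not in ("fasta", "clustal"):
        raise AlignmentError(f"format must be fasta|clustal, got {fmt!r}")
    handle = source if hasattr(source, "read") else io.StringIO(str(source))
    try:
        msa = AlignIO.read(handle, fmt)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {fmt} alignment: {exc}")
    ids = tuple(rec.id for rec in msa)
    seqs = tuple(str(rec.seq).upper() for rec in msa)
    if query_id:
        if query_id not in ids:
            raise AlignmentError(
                f"query id {query_id!r} not in alignment; available: {list(ids)}")
        query_row = ids.index(query_id)
    else:
        query_row = 0
    return Alignment(ids=ids, seqs=seqs, query_row=query_row)


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Fraction of matching positions over columns where both rows are
    non-gap (X counts as a gap). Zero shared columns gives identity 0."""
    matches = 0
    shared = 0
    for a, b in zip(seq1, seq2):
        if a in GAP_CHARS or b in GAP_CHARS or a == "X" or b == "X":
            continue
        shared += 1
        if a == b:
            matches += 1
    return matches / shared if shared else 0.0


def redundancy_filter(aln: Alignment, identity_threshold: float = 0.80) -> Alignment:
    """Greedy redundancy removal in input order at the given identity.

    The query row is processed first and always retained; any later row whose
    identity to some retained row exceeds the threshold is dropped.
    """
    order = [aln.query_row] + [i for i in range(aln.n_rows) if i != aln.query_row]
    retained: List[int] = []
    for i in order:
        if any(pairwise_identity(aln.seqs[i], aln.seqs[j]) > identity_threshold
               for j in retained):
            continue
        retained.append(i)
    retained_sorted = sorted(retained)
    return Alignment(
        ids=tuple(aln.ids[i] for i in retained_sorted),
        seqs=tuple(aln.seqs[i] for i in retained_sorted),
        query_row=retained_sorted.index(aln.query_row),
    )


def _column_residues(aln: Alignment, j: int) -> List[str]:
    return [c for c in aln.column(j) if c not in GAP_CHARS and c != "X"]


def column_conservation(aln: Alignment, query_position: int,
                        matrix: SubstitutionMatrix,
                        query_only: bool = False) -> float:
    """Conservation of one alignment column, in [0, 1].

    The raw score is the mean substitution score over all unordered pairs of
    non-gap residues in the column (or, with `query_only`, over pairs of the
    query residue with every other row), divided by 100 and clamped to [0, 1].
    """
    col = aln.column(query_position)
    if col[aln.query_row] in GAP_CHARS:
        raise ColumnDepthError(f"query has a gap at column {query_position}")
    residues = _column_residues(aln, query_position)
    if len(residues) < 2:
        raise ColumnDepthError(
            f"column {query_position} has {len(residues)} non-gap residues (< 2)")
    if query_only:
        q = col[aln.query_row]
        others = [c for i, c in enumerate(col)
                  if i != aln.query_row and c not in GAP_CHARS and c != "X"]
        pair_scores = [matrix.score(q, o) for o in others]
    else:
        pair_scores = [matrix.score(a, b) for a, b in combinations(residues, 2)]
    c_raw = float(np.mean(pair_scores))
    return float(np.clip(c_raw / 100.0, 0.0, 1.0))


def conservation_profile(aln: Alignment, chain_sequence: str,
                         matrix: SubstitutionMatrix,
                         query_only: bool = False) -> np.ndarray:
    """Per-structure-residue conservation scores, aligned to `chain_sequence`.

    The query row's ungapped sequence must equal the chain sequence exactly;
    columns too shallow to score fall back to 0 with a warning.
    """
    ungapped = aln.query_sequence()
    if ungapped != chain_sequence:
        for k, (a, b) in enumerate(zip(ungapped, chain_sequence)):
            if a != b:
                raise SequenceMismatchError(
                    f"alignment query and structure chain disagree at position "
                    f"{k}: {a!r} vs {b!r}")
        raise SequenceMismatchError(
            f"alignment query length {len(ungapped)} != chain length "
            f"{len(chain_sequence)}")
    scores = np.zeros(len(chain_sequence))
    qseq = aln.seqs[aln.query_row]
    pos = 0
    for j, c in enumerate(qseq):
        if c in GAP_CHARS:
            continue
        try:
            scores[pos] = column_conservation(aln, j, matrix, query_only=query_only)
        except ColumnDepthError:
            logger.warning("column %d too shallow to score; conservation set to 0", j)
            scores[pos] = 0.0
        pos += 1
    return scores
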