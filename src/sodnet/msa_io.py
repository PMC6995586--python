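"""Reading, validating and indexing protein multiple sequence alignments.

The coevolution model downstream works over a fixed 21-letter alphabet
(20 canonical amino acids plus the gap character ``-``).  Everything read
here is coerced onto that alphabet: lowercase letters are upper-cased,
``.`` and any non-canonical symbol (X, B, Z, U, O, ...) become gaps, and
the number of coercions is counted so no silent data mangling occurs.

Residue numbering is handled through a *column map*: the alignment columns
that are non-gap in a chosen reference row are mapped to 1-based residue
numbers (optionally offset), so that coupled pairs can be reported in the
numbering of, e.g., human SOD1 rather than in raw column indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger(__name__)

#: canonical 21-state alphabet; the gap is the last state.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
Q = len(ALPHABET)  # 21

_SYMBOL_TO_STATE = {s: i for i, s in enumerate(ALPHABET)}
GAP_STATE = _SYMBOL_TO_STATE[GAP]


@dataclass
class Alignment:
    """An MSA of M rows x L columns over the 21-state alphabet.

    Attributes
    ----------
    matrix:
        ``(M, L)`` uint8 array of state indices into :data:`ALPHABET`.
    ids:
        Per-row identifiers, length M.
    coercions:
        Number of input symbols that had to be coerced to gap.
    ref_id:
        Identifier of the reference row used for numbering, if any.
    column_map:
        Mapping alignment column (0-based) -> reference residue number
        (1-based); covers exactly the non-gap columns of the reference row.
    """

    matrix: np.ndarray
    ids: list[str]
    coercions: int = 0
    ref_id: str | None = None
    column_map: dict[int, int] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, i: int) -> str:
        return "".join(ALPHABET[s] for s in self.matrix[i])

    def sequences(self) -> list[str]:
        return [self.row(i) for i in range(self.n_sequences)]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D (M x L)")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids length does not match number of rows")
        if self.matrix.size and self.matrix.max() >= Q:
            raise ValueError("state index outside the 21-letter alphabet")


def encode_sequence(seq: str) -> tuple[np.ndarray, int]:
    """Encode one sequence into state indices, coercing unknowns to gap.

    Returns the encoded row and the number of coerced symbols.  Lowercase
    letters are upper-cased first (not counted as coercions when canonical);
    ``.`` and non-canonical letters map to the gap state.
    """
    states = np.empty(len(seq), dtype=np.uint8)
    coerced = 0
    for k, ch in enumerate(seq.upper()):
        s = _SYMBOL_TO_STATE.get(ch)
        if s is None:
            s = GAP_STATE
            coerced += 1
        states[k] = s
    return states, coerced


def from_sequences(seqs: list[str], ids: list[str] | None = None) -> Alignment:
    """Build an :class:`Alignment` from equal-length strings."""
    if not seqs:
        raise ValueError("empty alignment: no sequences given")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(seqs))]
    L = len(seqs[0])
    rows = []
    total_coerced = 0
    for sid, s in zip(ids, seqs):
        if len(s) != L:
            raise ValueError(
                f"ragged alignment: row '{sid}' has length {len(s)}, expected {L}"
            )
        row, c = encode_sequence(s)
        rows.append(row)
        total_coerced += c
    if total_coerced:
        logger.info("coerced %d non-standard symbols to gap", total_coerced)
    return Alignment(matrix=np.vstack(rows), ids=list(ids), coercions=total_coerced)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Rows must all have the same length (a hard error names the offending
    id otherwise); an empty file is a hard error.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if format == "fasta":
        # read records individually so ragged input produces a useful error
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(AlignIO.read(str(path), "stockholm"))
    if not records:
        raise ValueError(f"empty alignment file: {path}")
    return from_sequences([str(r.seq) for r in records], [r.id for r in records])


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment back out (gap character ``-``)."""
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    records = [
        SeqRecord(Seq(aln.row(i)), id=aln.ids[i], description="")
        for i in range(aln.n_sequences)
    ]
    msa = MultipleSeqAlignment(records)
    AlignIO.write(msa, str(path), format)


def map_columns(aln: Alignment, ref_id: str, offset: int = 1) -> Alignment:
    """Attach a column -> reference-residue-number map to the alignment.

    The map covers exactly the non-gap columns of the reference row; the
    first non-gap column receives number ``offset`` and numbering increases
    by one per non-gap column (1-based when ``offset=1``).
    """
    try:
        ref_row = aln.ids.index(ref_id)
    except ValueError:
        raise KeyError(f"reference id {ref_id!r} not present in alignment") from None
    states = aln.matrix[ref_row]
    column_map: dict[int, int] = {}
    resnum = offset
    for col in range(aln.length):
        if states[col] != GAP_STATE:
            column_map[col] = resnum
            resnum += 1
    if not column_map:
        warnings.warn(f"reference row {ref_id!r} is all gaps; empty column map")
    return Alignment(
        matrix=aln.matrix,
        ids=aln.ids,
        coercions=aln.coercions,
        ref_id=ref_id,
        column_map=column_map,
    )
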