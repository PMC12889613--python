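"""Encoded multiple sequence alignments of kinase catalytic domains.

Sequences are stored as integer matrices over a fixed alphabet of 21 Potts
states: the 20 standard amino acids plus the alignment gap, which is treated
as an ordinary state so that gapped columns can be threaded like any other.
FASTA and A2M input are supported; in A2M, lowercase letters and ``.`` mark
insertions relative to the match columns and are dropped on reading, while
``-`` is a gap in a match column and is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Ordered residue letters; the gap is the last Potts state.
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

_ENCODE = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
_ENCODE["."] = _ENCODE["-"]
_ENCODE["X"] = _ENCODE["-"]  # unknown residue threads as gap


@dataclass
class Alignment:
    """Integer-encoded alignment: ``seqs[n, i]`` is the state of sequence n at column i."""

    seqs: np.ndarray
    ids: list[str]
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        self.seqs = np.ascontiguousarray(self.seqs, dtype=np.int64)
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D (n_sequences, L) array")
        if self.q < 2:
            raise ValueError("alphabet must have at least 2 states")
        if self.L < 1:
            raise ValueError("alignment must have at least one column")
        if len(self.ids) != self.seqs.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for {self.seqs.shape[0]} sequences"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if self.seqs.size and (self.seqs.min() < 0 or self.seqs.max() >= self.q):
            raise ValueError(f"encoded states must lie in [0, {self.q})")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    def sequence(self, seq_id: str) -> np.ndarray:
        """Return the encoded sequence for one id."""
        try:
            idx = self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None
        return self.seqs[idx]

    def decode(self, row: int) -> str:
        return "".join(self.alphabet[a] for a in self.seqs[row])


def encode_sequence(seq: str, alphabet: str = PROTEIN_ALPHABET) -> np.ndarray:
    """Encode an aligned (match-column only) sequence string to integer states."""
    if alphabet is PROTEIN_ALPHABET:
        table = _ENCODE
    else:
        table = {c: i for i, c in enumerate(alphabet)}
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        try:
            out[i] = table[c.upper()]
        except KeyError:
            raise ValueError(f"unknown residue {c!r} at column {i}") from None
    return out


def _strip_inserts(raw: str) -> str:
    # A2M: lowercase and "." are insert states relative to the match columns
    return "".join(c for c in raw if not (c.islower() or c == "."))


def read_alignment(path, L: int | None = None, alphabet: str = PROTEIN_ALPHABET) -> Alignment:
    """Read a FASTA/A2M alignment, rejecting sequences whose match length differs from L.

    Parameters
    ----------
    path : str or Path
        FASTA or A2M file.
    L : int, optional
        Expected number of match columns.  Defaults to the length of the first
        sequence; records of any other length are dropped with a logged warning.
    """
    rows, ids, rejected = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = _strip_inserts(str(rec.seq))
        if L is None:
            L = len(s)
        if len(s) != L:
            rejected.append(rec.id)
            continue
        rows.append(encode_sequence(s, alphabet))
        ids.append(rec.id)
    if rejected:
        logger.warning(
            "dropped %d sequence(s) with length != %d: %s",
            len(rejected), L, ", ".join(rejected),
        )
    if not rows:
        raise ValueError(f"no usable sequences in {path}")
    return Alignment(np.array(rows), ids, alphabet)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as FASTA (gap as ``-``)."""
    with open(path, "w") as fh:
        for i, seq_id in enumerate(aln.ids):
            fh.write(f">{seq_id}\n{aln.decode(i)}\n")
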