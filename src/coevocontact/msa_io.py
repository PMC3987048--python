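"""Alignment input/output and symbol encoding.

The working alphabet has 21 states: the 20 canonical amino acids in
alphabetical one-letter order (``ACDEFGHIKLMNPQRSTVWY`` -> codes 0..19)
followed by the gap class (code 20).  Every non-canonical symbol --
``-``, ``.``, ambiguity codes (B, J, O, U, X, Z), lowercase letters --
is pooled into the gap class so that the state space stays fixed at 21.

Residue positions are 1-based in all outputs.  Row 0 of an alignment is
the target sequence; gap columns of the target are *not* removed -- the
alignment is assumed to be matched to the target already.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, MsaFormatError

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
GAP_CODE = 20
N_STATES = 21

_CODE_OF = np.full(256, GAP_CODE, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE_OF[ord(_c)] = _i


@dataclass(frozen=True)
class Alignment:
    """An encoded multiple sequence alignment.

    Attributes
    ----------
    rows : tuple of str
        The aligned sequences as given, all of identical length.
    encoded : numpy.ndarray
        ``M x L`` int8 matrix with codes ``0..20`` (20 = gap class).
    """

    rows: tuple
    encoded: np.ndarray

    @property
    def M(self) -> int:
        return self.encoded.shape[0]

    @property
    def L(self) -> int:
        return self.encoded.shape[1]

    @property
    def target_residues(self) -> str:
        return self.rows[0]

    def __post_init__(self):
        if self.encoded.ndim != 2 or self.encoded.shape[0] < 1 or self.encoded.shape[1] < 1:
            raise MsaFormatError("alignment must have at least one row and one column")


def encode_symbols(rows: Iterable[str]) -> np.ndarray:
    """Encode equal-length symbol strings into an ``M x L`` int8 code matrix.

    Canonical amino acids map to 0..19 (alphabetical order); everything
    else, including gaps and ambiguity codes, maps to 20.
    """
    rows = list(rows)
    if not rows:
        raise EmptyInputError("no sequences to encode")
    L = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != L:
            raise MsaFormatError(
                f"ragged alignment: row {k + 1} has length {len(r)}, expected {L}"
            )
    buf = np.frombuffer("".join(rows).encode("latin-1"), dtype=np.uint8)
    return _CODE_OF[buf].reshape(len(rows), L)


def decode_row(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_symbols` for one row; code 20 becomes ``-``."""
    return "".join(ALPHABET[c] if c < GAP_CODE else GAP for c in codes)


def make_alignment(rows: Iterable[str]) -> Alignment:
    rows = tuple(rows)
    return Alignment(rows=rows, encoded=encode_symbols(rows))


def _as_text_handle(source) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    if isinstance(source, bytes):
        return io.StringIO(source.decode("ascii"))
    if isinstance(source, io.BufferedIOBase) or (
        hasattr(source, "read") and isinstance(source.read(0), bytes)
    ):
        return io.TextIOWrapper(source, encoding="ascii")
    return source


def read_alignment(source, format: str = "auto") -> Alignment:
    """Read an alignment from a stream, string or path-open handle.

    Parameters
    ----------
    source : text/bytes stream or str
        Alignment content.  ``format="flat"`` expects one aligned
        sequence per line with no headers, first line = target;
        ``format="fasta"`` expects aligned FASTA records;
        ``format="auto"`` picks FASTA when the first non-blank
        character is ``>``.
    """
    handle = _as_text_handle(source)
    text = handle.read()
    if not text.strip():
        raise EmptyInputError("empty alignment input")
    if format == "auto":
        format = "fasta" if text.lstrip()[0] == ">" else "flat"
    if format == "fasta":
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise EmptyInputError("no FASTA records found")
        rows = [str(rec.seq) for rec in records]
        L = len(rows[0])
        for rec, row in zip(records, rows):
            if len(row) != L:
                raise MsaFormatError(
                    f"ragged alignment: record '{rec.id}' has length {len(row)}, expected {L}"
                )
    elif format == "flat":
        rows = [line.strip() for line in text.splitlines() if line.strip()]
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    return make_alignment(rows)


def write_contacts(contacts, sink: IO[str]) -> None:
    """Write a ranked contact list as TSV.

    One line per pair: ``i  res_i  j  res_j  raw  corrected`` with
    1-based residue indices, i < j, scores printed to 6 significant
    digits, lines in ranking order (descending corrected score).
    """
    target = getattr(contacts, "target_residues", None)

    def res(idx1: int) -> str:
        if target is None:
            return GAP
        return target[idx1 - 1]

    for e in contacts.entries:
        sink.write(f"{e.i}\t{res(e.i)}\t{e.j}\t{res(e.j)}\t{e.raw:.6g}\t{e.corrected:.6g}\n")
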