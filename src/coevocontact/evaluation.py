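"""CASP-style evaluation: true contacts from structures, top-L/n precision.

Two residues are in contact when their Cbeta-Cbeta distance (Calpha for
glycine) is strictly below the threshold (8 Angstrom by default).
Precision is reported for the top floor(L/n) predictions, n in
{1, 2, 5, 10}, within sequence-separation bands j - i > sep, sep in
{4, 8, 11, 23}.

Note the two separation conventions, both kept on purpose: the
*predictor* reports pairs with j - i >= mincontsep, while *evaluation*
bands use the strict j - i > sep filter.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Set, Tuple

import numpy as np
from Bio.PDB import PDBParser

from .errors import CoevoError

DEFAULT_THRESHOLD = 8.0
TOP_FRACTIONS = (1, 2, 5, 10)
SEPARATIONS = (4, 8, 11, 23)


@dataclass(frozen=True)
class ContactMap:
    L: int
    pairs: Set[Tuple[int, int]]     # unordered (i, j), i < j, 1-based
    threshold: float = DEFAULT_THRESHOLD
    atom_rule: str = "Cbeta, Calpha for glycine"

    def __post_init__(self):
        for i, j in self.pairs:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"contact ({i},{j}) outside [1, {self.L}] or not i<j")


@dataclass(frozen=True)
class PrecisionReport:
    """Precision [%] per (n, sep) cell; None marks a cell with no admissible pairs."""

    values: Dict[Tuple[int, int], Optional[float]]
    counts: Dict[Tuple[int, int], int]
    L: int


def contacts_from_structure(
    coords: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ContactMap:
    """Contact map from one representative coordinate per residue (strict <)."""
    coords = np.asarray(coords, dtype=float)
    L = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    pairs = {
        (i + 1, j + 1) for i in range(L) for j in range(i + 1, L) if d[i, j] < threshold
    }
    return ContactMap(L=L, pairs=pairs, threshold=threshold)


def read_structure(source, chain: str) -> np.ndarray:
    """Representative coordinates (Cbeta, Calpha for glycine/missing-Cbeta)
    for each residue of a chain, first model only.

    Altloc selection: highest occupancy, ties broken alphabetically.
    """
    if isinstance(source, str) and "\n" not in source:
        handle = open(source)
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(PERMISSIVE=True, QUIET=True).get_structure("s", handle)
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise CoevoError(f"chain {chain!r} not found in structure")
    coords = []
    for residue in model[chain]:
        if residue.id[0].strip():          # skip HETATM / water
            continue
        name = "CA" if residue.get_resname() == "GLY" else "CB"
        atom = _pick_atom(residue, name)
        if atom is None:
            atom = _pick_atom(residue, "CA")
        if atom is None:
            raise CoevoError(
                f"residue {residue.get_resname()} {residue.id[1]} has neither CB nor CA"
            )
        coords.append(atom)
    return np.asarray(coords, dtype=float)


def _pick_atom(residue, name: str):
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        children = sorted(
            atom.child_dict.items(), key=lambda kv: (-kv[1].get_occupancy(), kv[0])
        )
        atom = children[0][1]
    return atom.get_coord()


def contact_map_from_tsv(source, L: int, threshold: float = DEFAULT_THRESHOLD) -> ContactMap:
    """Load a ContactMap from a two-column TSV of 1-based index pairs."""
    if isinstance(source, str):
        source = io.StringIO(source)
    pairs = set()
    for line in source:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j = (int(x) for x in line.split()[:2])
        if i > j:
            i, j = j, i
        pairs.add((i, j))
    return ContactMap(L=L, pairs=pairs, threshold=threshold)


def precision_report(
    pred,
    truth: ContactMap,
    L: int,
    fractions=TOP_FRACTIONS,
    separations=SEPARATIONS,
) -> PrecisionReport:
    """Precision of the top floor(L/n) predictions per separation band.

    For each (n, sep): walk the ranked predictions, keep pairs with
    j - i > sep, stop after floor(L/n) of them; precision is the
    percentage that are true contacts.  Cells with zero admissible
    pairs are reported as None (missing), not 0.
    """
    values: Dict[Tuple[int, int], Optional[float]] = {}
    counts: Dict[Tuple[int, int], int] = {}
    entries = list(pred.entries) if hasattr(pred, "entries") else list(pred)
    for sep in separations:
        admissible = [e for e in entries if e.j - e.i > sep]
        for n in fractions:
            take = math.floor(L / n)
            taken = admissible[:take]
            key = (n, sep)
            counts[key] = len(taken)
            if not taken:
                values[key] = None
                continue
            tp = sum(1 for e in taken if (e.i, e.j) in truth.pairs)
            values[key] = 100.0 * tp / len(taken)
    return PrecisionReport(values=values, counts=counts, L=L)
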