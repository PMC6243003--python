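"""Protein length, average molecular weight and isoelectric point.

Masses are average (not monoisotopic) residue masses; the pI solver finds the
pH of zero net charge by bisection over Henderson-Hasselbalch terms with a
Bjellqvist-style pKa table.  The pKa table is a declared constant so results
are pinned; it is an external convention, replaceable per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights

WATER = 18.015

#: Average residue masses (free amino-acid average mass minus one water).
RESIDUE_MASSES: dict[str, float] = {
    aa: mass - 18.0153 for aa, mass in protein_weights.items()
}

#: Average mass contributed by an unknown residue (X).
UNKNOWN_RESIDUE_MASS = 110.0

#: Positive (N-terminus and basic side chains) and negative (C-terminus and
#: acidic side chains) pKa values.
DEFAULT_PKA: dict[str, float] = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
}

_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    mw: float
    pi: float


def molecular_weight(sequence: str) -> float:
    """Sum of average residue masses plus one water (Daltons)."""
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    total = WATER
    for ch in sequence:
        if ch in RESIDUE_MASSES:
            total += RESIDUE_MASSES[ch]
        elif ch == "X":
            warnings.warn("unknown residue X assigned average mass", stacklevel=2)
            total += UNKNOWN_RESIDUE_MASS
        else:
            raise ValueError(f"unknown residue {ch!r} in sequence")
    return total


def net_charge(sequence: str, ph: float, pka: dict[str, float] = DEFAULT_PKA) -> float:
    """Net charge at ``ph``: positive HH terms minus negative HH terms.

    Residues B/Z/X carry no charge term.
    """
    counts = {aa: sequence.count(aa) for aa in "DECYHKR"}
    charge = 0.0
    for key in _POSITIVE:
        n = 1 if key == "Nterm" else counts.get(key, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[key]))
    for key in _NEGATIVE:
        n = 1 if key == "Cterm" else counts.get(key, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[key] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: dict[str, float] = DEFAULT_PKA,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    if not sequence:
        raise ValueError("empty sequence has no isoelectric point")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_properties(protein_id: str, sequence: str) -> ProteinProperties:
    return ProteinProperties(
        protein_id,
        len(sequence),
        molecular_weight(sequence),
        isoelectric_point(sequence),
    )
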