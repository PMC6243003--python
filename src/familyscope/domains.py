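"""WRKY domain detection by motif grammar.

A WRKY domain is anchored by the heptapeptide (canonically ``WRKYGQK``) and
completed by a C-terminal zinc finger whose coordinating residues follow the
pattern ``C X{n1} C X{n2} H X (H|C)``.  The spacer lengths (n1, n2) and the
terminal residue (H for C2H2, C for C2HC fingers) carry the group signal used
downstream by the classifier.  The scanner is a closed grammar: only the
variant heptapeptides observed in the family are accepted, and the spacer
ranges cover every signature seen in Vigna WRKYs with no slack.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

#: Accepted heptapeptide variants (closed set; extensible via function args).
HEPTAPEPTIDE_VARIANTS: tuple[str, ...] = (
    "WRKYGQK",
    "WRKYGKK",
    "WRKYGEK",
    "WKKYGQK",
    "SRKYGQK",
)

#: Zinc-finger spacer ranges: residues between C1-C2 and C2-first terminal.
N1_RANGE = (4, 7)
N2_RANGE = (21, 30)

#: Residues between a lone zinc finger and the nearest upstream heptapeptide
#: for them to be considered the same (truncated) domain.
HEPTAPEPTIDE_LOOKBACK = 30

#: Default search window (residues) for the finger downstream of a heptapeptide.
FINGER_WINDOW = 90

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_SIGNATURE_RE = re.compile(r"^CX(\d+)CX(\d+)HX([HC])$")


@dataclass(frozen=True)
class HeptapeptideMatch:
    protein_id: str
    start: int  # 0-based residue index
    variant: str


@dataclass(frozen=True)
class ZincFinger:
    c1: int
    c2: int
    n1: int
    n2: int
    h1: int  # first terminal residue (always H)
    terminal: int  # last coordinating residue (H or C)
    finger_class: str  # "C2H2" | "C2HC"

    @property
    def signature(self) -> str:
        tail = "H" if self.finger_class == "C2H2" else "C"
        return f"CX{self.n1}CX{self.n2}HX{tail}"


def parse_signature(signature: str) -> tuple[int, int, str]:
    """Parse a ``CX{n1}CX{n2}HX{H|C}`` signature into (n1, n2, finger_class)."""
    m = _SIGNATURE_RE.match(signature)
    if not m:
        raise ValueError(f"not a zinc-finger signature: {signature!r}")
    n1, n2, tail = int(m.group(1)), int(m.group(2)), m.group(3)
    return n1, n2, "C2H2" if tail == "H" else "C2HC"


@dataclass(frozen=True)
class WrkyDomain:
    protein_id: str
    heptapeptide: Optional[HeptapeptideMatch]
    zinc_finger: Optional[ZincFinger]
    domain_start: int
    domain_end: int  # inclusive residue index of the last domain residue
    completeness: str  # full | missing_heptapeptide | missing_zinc_finger
    role_in_protein: str = "single"  # NTWD | CTWD | single

    def __post_init__(self) -> None:
        if self.heptapeptide is None and self.zinc_finger is None:
            raise ValueError("a WRKY domain needs a heptapeptide or a finger")

    @property
    def signature(self) -> Optional[str]:
        return self.zinc_finger.signature if self.zinc_finger else None


def find_heptapeptides(
    sequence: str,
    variants: tuple[str, ...] = HEPTAPEPTIDE_VARIANTS,
    protein_id: str = "",
) -> list[HeptapeptideMatch]:
    """All non-overlapping heptapeptide matches, resolved leftmost-first."""
    hits: list[HeptapeptideMatch] = []
    i, n = 0, len(sequence)
    while i <= n - 7:
        window = sequence[i : i + 7]
        if window in variants:
            hits.append(HeptapeptideMatch(protein_id, i, window))
            i += 7
        else:
            i += 1
    return hits


def find_zinc_finger(
    sequence: str,
    search_start: int = 0,
    window: int = FINGER_WINDOW,
    n1_range: tuple[int, int] = N1_RANGE,
    n2_range: tuple[int, int] = N2_RANGE,
) -> Optional[ZincFinger]:
    """First zinc finger with C1 in ``[search_start, search_start + window)``.

    Candidates sharing C1 are resolved smallest n1 first, then smallest n2.
    The first terminal residue must be H; the last may be H (C2H2) or C (C2HC).
    Returns None when no finger fits, which is a valid outcome.
    """
    n = len(sequence)
    stop = min(n, search_start + window)
    for c1 in range(max(search_start, 0), stop):
        if sequence[c1] != "C":
            continue
        for n1 in range(n1_range[0], n1_range[1] + 1):
            c2 = c1 + 1 + n1
            if c2 >= n or sequence[c2] != "C":
                continue
            for n2 in range(n2_range[0], n2_range[1] + 1):
                h1 = c2 + 1 + n2
                term = h1 + 2
                if term >= n:
                    break
                if sequence[h1] != "H":
                    continue
                if sequence[term] == "H":
                    cls = "C2H2"
                elif sequence[term] == "C":
                    cls = "C2HC"
                else:
                    continue
                return ZincFinger(c1, c2, n1, n2, h1, term, cls)
    return None


def scan_protein(
    protein_id: str,
    sequence: str,
    variants: tuple[str, ...] = HEPTAPEPTIDE_VARIANTS,
    finger_window: int = FINGER_WINDOW,
    lookback: int = HEPTAPEPTIDE_LOOKBACK,
) -> list[WrkyDomain]:
    """Detect every WRKY domain of a protein, flagging truncations.

    Heptapeptides are paired with the first finger starting within
    ``finger_window`` residues downstream; unpaired heptapeptides become
    ``missing_zinc_finger`` domains.  Fingers with no heptapeptide within
    ``lookback`` residues upstream become ``missing_heptapeptide`` domains.
    With two or more domains the first is the NTWD and the rest CTWDs.
    """
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise ValueError(
            f"{protein_id or 'protein'}: non-amino-acid characters "
            f"{sorted(bad)!r} in sequence"
        )

    heptas = find_heptapeptides(sequence, variants, protein_id)
    domains: list[WrkyDomain] = []
    claimed_c1: set[int] = set()
    for h in heptas:
        zf = find_zinc_finger(sequence, h.start + 7, finger_window)
        if zf is not None and zf.c1 not in claimed_c1:
            claimed_c1.add(zf.c1)
            domains.append(
                WrkyDomain(protein_id, h, zf, h.start, zf.terminal, "full")
            )
        else:
            domains.append(
                WrkyDomain(
                    protein_id, h, None, h.start, h.start + 6,
                    "missing_zinc_finger",
                )
            )

    # Orphan fingers: greedy leftmost scan of the whole sequence.
    pos = 0
    while pos < len(sequence):
        zf = find_zinc_finger(sequence, pos, window=len(sequence) - pos)
        if zf is None:
            break
        if zf.c1 not in claimed_c1:
            upstream = any(
                zf.c1 - (h.start + 7) <= lookback and h.start + 7 <= zf.c1
                for h in heptas
            )
            if not upstream:
                domains.append(
                    WrkyDomain(
                        protein_id, None, zf, zf.c1, zf.terminal,
                        "missing_heptapeptide",
                    )
                )
            claimed_c1.add(zf.c1)
        pos = zf.terminal + 1

    domains.sort(key=lambda d: d.domain_start)
    if len(domains) >= 2:
        domains = [
            WrkyDomain(
                d.protein_id, d.heptapeptide, d.zinc_finger,
                d.domain_start, d.domain_end, d.completeness,
                "NTWD" if i == 0 else "CTWD",
            )
            for i, d in enumerate(domains)
        ]
    return domains
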