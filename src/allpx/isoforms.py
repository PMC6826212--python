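"""Phospho-isoform enumeration over the nine modifiable residue classes.

An "all-pX" search considers phosphorylation of Ser, Thr, Tyr, His,
Asp, Glu, Lys, Arg and Cys.  A peptide with n modifiable positions
yields 2**n candidate modification states (the unmodified form
included), which is the combinatorial cost this module makes explicit.
In decoy mode, Cys is replaced by the non-phosphorylatable Ala so that
apparent pAla calls calibrate random site assignment; the transform is
alphabet-level so every downstream operation reuses the same code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

#: The nine residue classes considered phosphorylatable in an all-pX search.
ALL_CLASSES = ("S", "T", "Y", "H", "D", "E", "K", "R", "C")
#: Canonical subset.
CANONICAL_CLASSES = ("S", "T", "Y")
#: The decoy residue: alanine cannot be phosphorylated.
DECOY_RESIDUE = "A"

# Enumeration refuses more modifiable positions than this without an
# explicit override: 2**n candidates quickly destroys statistical power.
MAX_MODIFIABLE_DEFAULT = 20


@dataclass(frozen=True)
class ModifiableAlphabet:
    """Ordered, duplicate-free set of residue letters open to phosphorylation."""

    residue_classes: tuple[str, ...] = ALL_CLASSES

    def __post_init__(self):
        if not self.residue_classes:
            raise ValueError("alphabet must be non-empty")
        if len(set(self.residue_classes)) != len(self.residue_classes):
            raise ValueError("alphabet contains duplicate residue classes")

    def __contains__(self, residue: str) -> bool:
        return residue in self.residue_classes

    def decoy(self) -> "ModifiableAlphabet":
        """Decoy transform: drop Cys, add Ala (order-preserving)."""
        classes = tuple(c for c in self.residue_classes if c != "C")
        if DECOY_RESIDUE not in classes:
            classes = classes + (DECOY_RESIDUE,)
        return ModifiableAlphabet(classes)


#: All nine classes, ready to use.
ALL_PX = ModifiableAlphabet(ALL_CLASSES)
#: Decoy alphabet (pCys -> pAla).
ALL_PX_DECOY = ALL_PX.decoy()


@dataclass(frozen=True)
class PhosphoIsoform:
    """A peptide plus a set of phosphorylated positions (1-based)."""

    sequence: str
    phospho_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        for p in self.phospho_positions:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(f"phospho position {p} outside sequence bounds")

    @property
    def k(self) -> int:
        return len(self.phospho_positions)

    def sites(self) -> list[tuple[int, str]]:
        """Sorted (position, residue) pairs of the phosphorylated sites."""
        return [(p, self.sequence[p - 1]) for p in sorted(self.phospho_positions)]

    def annotated(self) -> str:
        """Sequence with phosphorylated residues lower-cased, e.g. ``AsDK``."""
        return "".join(
            ch.lower() if (i + 1) in self.phospho_positions else ch
            for i, ch in enumerate(self.sequence)
        )


def modifiable_positions(sequence: str, alphabet: ModifiableAlphabet = ALL_PX) -> list[int]:
    """1-based positions whose residue belongs to the alphabet."""
    return [i for i, ch in enumerate(sequence, start=1) if ch in alphabet]


def count_candidates(sequence: str, alphabet: ModifiableAlphabet = ALL_PX) -> int:
    """Number of candidate modification states: 2**n, unmodified form included."""
    return 2 ** len(modifiable_positions(sequence, alphabet))


def enumerate_isoforms(
    sequence: str,
    k_phospho: int,
    alphabet: ModifiableAlphabet = ALL_PX,
    *,
    max_modifiable: int = MAX_MODIFIABLE_DEFAULT,
) -> list[PhosphoIsoform]:
    """All C(n, k) isoforms with exactly ``k_phospho`` phosphorylated positions.

    Deterministic lexicographic order by position tuple.  Refuses
    peptides with more than ``max_modifiable`` candidate positions to
    guard against the 2**n blow-up; raise the cap explicitly if needed.
    """
    positions = modifiable_positions(sequence, alphabet)
    n = len(positions)
    if n > max_modifiable:
        raise ValueError(
            f"{n} modifiable positions exceeds the guard rail of {max_modifiable}; "
            "pass max_modifiable explicitly to override"
        )
    if k_phospho < 0 or k_phospho > n:
        raise ValueError(f"k_phospho={k_phospho} outside 0..{n} for this sequence")
    return [
        PhosphoIsoform(sequence, frozenset(combo))
        for combo in itertools.combinations(positions, k_phospho)
    ]


def enumerate_all(
    sequence: str,
    alphabet: ModifiableAlphabet = ALL_PX,
    *,
    max_modifiable: int = MAX_MODIFIABLE_DEFAULT,
) -> list[PhosphoIsoform]:
    """Every modification state (all k), in increasing-k lexicographic order."""
    n = len(modifiable_positions(sequence, alphabet))
    out: list[PhosphoIsoform] = []
    for k in range(n + 1):
        out.extend(enumerate_isoforms(sequence, k, alphabet, max_modifiable=max_modifiable))
    return out
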