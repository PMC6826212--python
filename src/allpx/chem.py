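"""Monoisotopic mass bookkeeping and theoretical ion generation.

All computation is monoisotopic; nominal values (80/98/116 amu and the
like) are display conventions only.  Residue masses come from
:mod:`pyteomics.mass`; the handful of constants specific to
phosphopeptide work (the HPO3 delta, the precursor neutral-loss ladder,
diagnostic immonium arithmetic) live here.

Ion series conventions
----------------------
* b/y for beam-type collisional dissociation (HCD).
* c/z for electron-transfer dissociation; the z ion is generated as the
  z-dot radical (z+1), the common ETD readout.  ``c = b + NH3`` and
  ``z• = y − NH3 + H`` at equal index and charge.
* Neutral losses (−HPO3, −H3PO4) are generated only from fragments
  carrying at least one phospho group; side-chain water/ammonia losses
  are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from pyteomics import mass as _pt_mass

# Residue monoisotopic masses (Da), 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

PROTON = 1.00727646688          # Da, mass of H+
WATER = 18.0105646863           # Da, H2O
NH3 = 17.0265491015             # Da, ammonia (b -> c shift)
H_ATOM = 1.0078250319           # Da, hydrogen atom (z -> z-dot shift)
CO = 27.9949146221              # Da, carbon monoxide (immonium arithmetic)
PHOSPHO = 79.96633089           # Da, HPO3 added by phosphorylation
CARBAMIDOMETHYL = 57.02146373   # Da, fixed Cys alkylation (optional)

#: Precursor neutral-loss ladder: HPO3, H3PO4, H3PO4 + H2O.
NEUTRAL_LOSSES: dict[str, float] = {
    "HPO3": PHOSPHO,
    "H3PO4": PHOSPHO + WATER,
    "H3PO4+H2O": PHOSPHO + 2 * WATER,
}

_Z_DOT_SHIFT = -NH3 + H_ATOM  # y -> z-dot

Series = Literal["b", "y", "c", "z"]


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for ch in sequence:
        if ch not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue letter {ch!r} in sequence")


def peptide_mass(
    sequence: str,
    n_phospho: int = 0,
    *,
    carbamidomethyl_cys: bool = False,
) -> float:
    """Neutral monoisotopic mass of a peptide carrying ``n_phospho`` HPO3 groups."""
    _check_sequence(sequence)
    if n_phospho < 0:
        raise ValueError("n_phospho must be >= 0")
    m = sum(RESIDUE_MASSES[ch] for ch in sequence) + WATER
    if carbamidomethyl_cys:
        m += CARBAMIDOMETHYL * sequence.count("C")
    return m + n_phospho * PHOSPHO


def immonium_mz(residue_letter: str, phosphorylated: bool = False) -> float:
    """m/z of the (phospho)immonium ion of a residue: residue − CO + proton."""
    if residue_letter not in RESIDUE_MASSES:
        raise ValueError(f"unknown residue letter {residue_letter!r}")
    m = RESIDUE_MASSES[residue_letter]
    if phosphorylated:
        m += PHOSPHO
    return m - CO + PROTON


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment: series, ordinal index, charge, m/z."""

    series: str
    index: int
    charge: int
    mz: float
    neutral_loss_applied: str = "none"

    def label(self) -> str:
        suffix = "" if self.neutral_loss_applied == "none" else f"-{self.neutral_loss_applied}"
        return f"{self.series}{self.index}{suffix}^{self.charge}"


def _prefix_masses(sequence: str, phospho_positions: frozenset[int],
                   carbamidomethyl_cys: bool) -> list[float]:
    """Cumulative residue masses for prefixes of length 1..L (mods included)."""
    out = []
    acc = 0.0
    for i, ch in enumerate(sequence, start=1):
        acc += RESIDUE_MASSES[ch]
        if carbamidomethyl_cys and ch == "C":
            acc += CARBAMIDOMETHYL
        if i in phospho_positions:
            acc += PHOSPHO
        out.append(acc)
    return out


def fragment_ions(
    isoform,
    series_set: Iterable[Series] = ("b", "y"),
    max_charge: int = 1,
    include_neutral_losses: bool = False,
    *,
    carbamidomethyl_cys: bool = False,
) -> list[FragmentIon]:
    """Theoretical fragment ions of a phospho-isoform.

    ``isoform`` needs ``sequence`` and ``phospho_positions`` attributes
    (1-based positions).  For each series in ``series_set`` and each
    cleavage index ``1..L−1``, one ion per charge state ``1..max_charge``
    is produced; the phospho mass is included for fragments spanning a
    modified position.  With ``include_neutral_losses``, −HPO3 and
    −H3PO4 variants are added for phospho-containing fragments.
    """
    series_set = tuple(series_set)
    if not series_set:
        raise ValueError("series_set must be non-empty")
    bad = set(series_set) - {"b", "y", "c", "z"}
    if bad:
        raise ValueError(f"unsupported ion series: {sorted(bad)}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    sequence = isoform.sequence
    _check_sequence(sequence)
    positions = frozenset(isoform.phospho_positions)
    L = len(sequence)
    prefix = _prefix_masses(sequence, positions, carbamidomethyl_cys)
    total = prefix[-1] + WATER

    ions: list[FragmentIon] = []
    for i in range(1, L):
        # Neutral masses of the N-terminal (b) and C-terminal (y) pieces.
        b_neutral = prefix[i - 1]
        y_neutral = total - b_neutral
        n_phos_prefix = sum(1 for p in positions if p <= i)
        n_phos_suffix = len(positions) - n_phos_prefix
        for series in series_set:
            if series == "b":
                neutral, idx, n_phos = b_neutral, i, n_phos_prefix
            elif series == "c":
                neutral, idx, n_phos = b_neutral + NH3, i, n_phos_prefix
            elif series == "y":
                neutral, idx, n_phos = y_neutral, L - i, n_phos_suffix
            else:  # z-dot
                neutral, idx, n_phos = y_neutral + _Z_DOT_SHIFT, L - i, n_phos_suffix
            variants = [("none", neutral)]
            if include_neutral_losses and n_phos >= 1:
                variants.append(("HPO3", neutral - NEUTRAL_LOSSES["HPO3"]))
                variants.append(("H3PO4", neutral - NEUTRAL_LOSSES["H3PO4"]))
            for loss, nm in variants:
                for z in range(1, max_charge + 1):
                    ions.append(FragmentIon(series, idx, z, (nm + z * PROTON) / z, loss))
    return ions
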