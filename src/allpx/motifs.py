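"""±7-residue window extraction and motif-x-style iterative enrichment.

Each unique phosphosite contributes a 15-mer window (positions −7..+7,
the modified residue at the centre); windows truncated by a protein
terminus are padded with ``-``, which never counts toward any residue's
frequency.  Identical windows are merged so motif input is
non-redundant.

Enrichment follows the greedy motif-x recursion: repeatedly fix the
(position, residue) cell with the smallest binomial upper-tail p-value
below the significance threshold (subject to a minimum occurrence
count), restrict foreground and background to matching windows, and
recurse; when no cell qualifies, the accumulated constraints are
emitted as one motif and its matching windows are removed before the
search restarts.  Output motifs are therefore mutually exclusive over
the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_HALF = 7
WINDOW_LEN = 2 * WINDOW_HALF + 1
PAD = "-"
CENTRE = WINDOW_HALF  # string index of position 0

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_MIN_OCCURRENCES = 20


def extract_windows(
    unique_sites: pd.DataFrame,
    protein_sequences: Mapping[str, str],
) -> list[str]:
    """Deduplicated 15-mer windows around unique sites.

    ``unique_sites`` needs columns ``protein``, ``position`` (1-based)
    and ``residue``; the residue at each position is verified against
    the protein sequence.  Order of first appearance is preserved.
    """
    seen: dict[str, None] = {}
    for row in unique_sites.itertuples(index=False):
        seq = protein_sequences[row.protein]
        idx = int(row.position) - 1
        if not 0 <= idx < len(seq):
            raise ValueError(f"position {row.position} outside {row.protein}")
        if seq[idx] != row.residue:
            raise ValueError(
                f"residue mismatch at {row.protein}:{row.position}: "
                f"site says {row.residue!r}, protein has {seq[idx]!r}"
            )
        left = max(0, idx - WINDOW_HALF)
        right = min(len(seq), idx + WINDOW_HALF + 1)
        window = (PAD * (WINDOW_HALF - (idx - left))
                  + seq[left:right]
                  + PAD * (WINDOW_HALF - (right - 1 - idx)))
        seen.setdefault(window)
    return list(seen)


@dataclass(frozen=True)
class MotifPattern:
    """One enriched motif: fixed (offset, residue) constraints + statistics."""

    constraints: tuple[tuple[int, str], ...]  # offsets relative to centre
    centre_residue: str
    foreground_matches: int
    foreground_size: int
    background_matches: int
    background_size: int
    fold_enrichment: float
    p_value: float

    def pattern(self) -> str:
        """motif-x dotted notation, e.g. ``......H L.......`` -> ``.......hL......``
        rendered with the centre residue lower-cased."""
        chars = [PAD if False else "." for _ in range(WINDOW_LEN)]
        chars[CENTRE] = self.centre_residue.lower()
        for off, res in self.constraints:
            chars[CENTRE + off] = res
        return "".join(chars)

    def matches(self, window: str) -> bool:
        return all(window[CENTRE + off] == res for off, res in self.constraints)


def _cell_counts(windows: Sequence[str]) -> np.ndarray:
    """WINDOW_LEN x 20 occurrence counts (padding excluded)."""
    counts = np.zeros((WINDOW_LEN, len(AMINO_ACIDS)), dtype=int)
    aa_index = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for w in windows:
        for i, ch in enumerate(w):
            j = aa_index.get(ch)
            if j is not None:
                counts[i, j] += 1
    return counts


def motif_enrich(
    foreground: Sequence[str],
    background: Sequence[str],
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[MotifPattern]:
    """Greedy iterative motif-x over pre-extracted windows."""
    fg = [w for w in foreground]
    bg = [w for w in background]
    if not fg:
        return []
    if len(bg) < len(fg):
        raise ValueError("background must be at least as large as foreground")
    centres = {w[CENTRE] for w in fg}
    if len(centres) != 1:
        raise ValueError("foreground windows must share one centre residue class")
    centre_residue = centres.pop()

    motifs: list[MotifPattern] = []
    while fg:
        sub_fg, sub_bg = list(fg), list(bg)
        constraints: list[tuple[int, str]] = []
        last_p = 1.0
        while True:
            best = _best_cell(sub_fg, sub_bg, min_occurrences, p_threshold)
            if best is None:
                break
            (pos, res), p = best
            constraints.append((pos - CENTRE, res))
            last_p = p
            sub_fg = [w for w in sub_fg if w[pos] == res]
            sub_bg = [w for w in sub_bg if w[pos] == res]
        if not constraints:
            break
        bg_matches = sum(
            all(w[CENTRE + off] == r for off, r in constraints) for w in bg
        )
        fg_frac = len(sub_fg) / len(fg)
        bg_frac = bg_matches / len(bg) if bg_matches else 0.0
        motifs.append(MotifPattern(
            constraints=tuple(constraints),
            centre_residue=centre_residue,
            foreground_matches=len(sub_fg),
            foreground_size=len(fg),
            background_matches=bg_matches,
            background_size=len(bg),
            fold_enrichment=(fg_frac / bg_frac) if bg_frac else float("inf"),
            p_value=last_p,
        ))
        consumed = {w for w in fg
                    if all(w[CENTRE + off] == r for off, r in constraints)}
        fg = [w for w in fg if w not in consumed]
        bg = [w for w in bg
              if not all(w[CENTRE + off] == r for off, r in constraints)]
    return motifs


def _best_cell(fg: Sequence[str], bg: Sequence[str], min_occurrences: int,
               p_threshold: float):
    """Most significant (position, residue) cell, or None."""
    if not fg or not bg:
        return None
    fg_counts = _cell_counts(fg)
    bg_counts = _cell_counts(bg)
    n_fg, n_bg = len(fg), len(bg)
    best = None
    for i in range(WINDOW_LEN):
        if i == CENTRE:
            continue
        for j, res in enumerate(AMINO_ACIDS):
            k = fg_counts[i, j]
            if k < min_occurrences:
                continue
            p_bg = bg_counts[i, j] / n_bg
            if p_bg <= 0.0:
                p_bg = 1.0 / (n_bg + 1)  # pseudo-rate for a residue unseen in bg
            p = float(stats.binom.sf(k - 1, n_fg, p_bg))
            if p <= p_threshold and (best is None or p < best[1]):
                best = ((i, res), p)
    return best


def logo_counts(windows: Sequence[str]) -> pd.DataFrame:
    """Position x residue count matrix for sequence-logo rendering.

    Rows are offsets −7..+7; columns the 20 residues plus the padding
    symbol.  At positions without padding, residue columns sum to the
    window count.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    cols = list(AMINO_ACIDS) + [PAD]
    counts = pd.DataFrame(0, index=range(-WINDOW_HALF, WINDOW_HALF + 1), columns=cols)
    for w in windows:
        for i, ch in enumerate(w):
            counts.loc[i - WINDOW_HALF, ch] += 1
    counts.index.name = "offset"
    return counts
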