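"""Precursor neutral-loss "triplet" scoring and phosphoimmonium scanning.

Phosphopeptide precursors commonly shed HPO3 (Δ80), H3PO4 (Δ98) and
H3PO4 + H2O (Δ116) under collisional activation.  Each MS2 scan is
assessed for the three loss peaks at (precursor_mz − Δ/z) within a mass
tolerance and a base-peak-relative intensity cut-off, giving a triplet
score of 0–3.  The Δ98 flag doubles as the acquisition trigger used in
neutral-loss-triggered EThcD methods.  Low-mass phosphoimmonium ions
(pTyr 216.04, pHis 190.04, ...) are scanned the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chem
from .localization import Spectrum

DEFAULT_TOLERANCE = 0.5       # Da
DEFAULT_CUTOFF_PCT = 5.0      # % of base peak; 2/5/10 are the standard set
DEFAULT_MIN_REL_INTENSITY = 5.0

#: Loss labels in ladder order.
LOSS_LABELS = ("HPO3", "H3PO4", "H3PO4+H2O")
#: Nominal display names keyed by label.
LOSS_NOMINAL = {"HPO3": 80, "H3PO4": 98, "H3PO4+H2O": 116}


@dataclass(frozen=True)
class TripletResult:
    scan_id: str
    flags: dict  # loss label -> bool
    triplet_score: int
    intensity_cutoff_used: float
    tolerance_used: float

    def __post_init__(self):
        assert self.triplet_score == sum(bool(v) for v in self.flags.values())


@dataclass(frozen=True)
class ImmoniumResult:
    scan_id: str
    flags: dict  # residue -> bool
    threshold_used: float


def _has_peak(spectrum: Spectrum, target_mz: float, tolerance: float,
              min_intensity: float) -> bool:
    if spectrum.n_peaks == 0:
        return False
    lo = np.searchsorted(spectrum.mz, target_mz - tolerance, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + tolerance, side="right")
    if hi <= lo:
        return False
    return bool((spectrum.intensity[lo:hi] >= min_intensity).any())


def triplet_score(
    spectrum: Spectrum,
    tolerance: float = DEFAULT_TOLERANCE,
    cutoff_pct: float = DEFAULT_CUTOFF_PCT,
    charge_mode: str = "precursor",
) -> TripletResult:
    """Flag the Δ80/Δ98/Δ116 precursor neutral-loss peaks of one scan.

    ``charge_mode``: "precursor" searches losses at the precursor's own
    charge only; "all" additionally searches every lower charge state;
    "singly" forces z = 1 (usable when the charge is unknown).
    Intensity comparison is inclusive (>= cutoff% of base peak).
    """
    if charge_mode == "singly":
        charges = [1]
    else:
        z = spectrum.precursor_charge
        if z < 1:
            raise ValueError("precursor charge required unless charge_mode='singly'")
        charges = [z] if charge_mode == "precursor" else list(range(1, z + 1))
    if not 0.0 < cutoff_pct < 100.0:
        raise ValueError("cutoff_pct must lie in (0, 100)")

    min_intensity = spectrum.base_peak_intensity() * cutoff_pct / 100.0
    flags = {}
    for label in LOSS_LABELS:
        delta = chem.NEUTRAL_LOSSES[label]
        flags[label] = any(
            _has_peak(spectrum, spectrum.precursor_mz - delta / z, tolerance, min_intensity)
            for z in charges
        )
    return TripletResult(
        scan_id=spectrum.scan_id,
        flags=flags,
        triplet_score=sum(flags.values()),
        intensity_cutoff_used=cutoff_pct,
        tolerance_used=tolerance,
    )


def nl98_trigger(spectrum: Spectrum, tolerance: float = DEFAULT_TOLERANCE,
                 cutoff_pct: float = DEFAULT_CUTOFF_PCT) -> bool:
    """True iff the Δ98 (H3PO4) precursor loss peak is present.

    Emulates the acquisition logic where a 98 amu neutral loss after
    HCD triggers EThcD re-fragmentation of the precursor.
    """
    return triplet_score(spectrum, tolerance, cutoff_pct).flags["H3PO4"]


def immonium_scan(
    spectrum: Spectrum,
    residue_list: Sequence[str],
    tolerance: float = DEFAULT_TOLERANCE,
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
) -> ImmoniumResult:
    """Per-residue phosphoimmonium ion presence at >= min relative intensity."""
    if not residue_list:
        raise ValueError("residue_list must be non-empty")
    min_intensity = spectrum.base_peak_intensity() * min_rel_intensity / 100.0
    flags = {
        res: _has_peak(spectrum, chem.immonium_mz(res, phosphorylated=True),
                       tolerance, min_intensity)
        for res in residue_list
    }
    return ImmoniumResult(spectrum.scan_id, flags, min_rel_intensity)


def triplet_summary(
    results: Iterable[TripletResult],
    residue_by_scan: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score distribution and loss-combination counts per residue class.

    ``residue_by_scan`` maps scan_id to the confidently localised
    residue class.  Returns (score_table, combination_table):
    score_table has per-residue percentages at triplet scores 0..3
    (rows sum to 100); combination_table counts each of the 8 possible
    flag combinations, labelled e.g. ``Δ80+Δ98``.
    """
    rows = []
    for r in results:
        if r.scan_id not in residue_by_scan:
            continue
        combo = "+".join(
            f"Δ{LOSS_NOMINAL[lab]}" for lab in LOSS_LABELS if r.flags[lab]
        ) or "none"
        rows.append({
            "residue": residue_by_scan[r.scan_id],
            "score": r.triplet_score,
            "combination": combo,
        })
    if not rows:
        import warnings
        warnings.warn("no triplet results joined to a localised site call")
        return pd.DataFrame(), pd.DataFrame()
    df = pd.DataFrame(rows)

    score_counts = (
        df.pivot_table(index="residue", columns="score", aggfunc="size", fill_value=0)
        .reindex(columns=[0, 1, 2, 3], fill_value=0)
    )
    score_pct = score_counts.div(score_counts.sum(axis=1), axis=0) * 100.0
    score_pct.columns = [f"score_{c}_pct" for c in score_pct.columns]

    combo_counts = (
        df.pivot_table(index="residue", columns="combination", aggfunc="size", fill_value=0)
    )
    return score_pct, combo_counts
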