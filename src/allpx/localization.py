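"""Phosphosite localisation by cumulative-binomial fragment matching.

For a peptide-spectrum match carrying k phospho groups, every isoform
placing k groups on the modifiable residues is scored against the
depth-filtered peak list.  With n_i theoretical ions of which k_i match
within the fragment tolerance, and per-ion chance-match probability
p = depth * 2 * tolerance / 100 (the expected fraction of each 100 m/z
window covered by retained peaks), the isoform's evidence is the upper
binomial tail P_i = P(X >= k_i | n_i, p).  Isoform probabilities are
the normalised reciprocals w_i = (1/P_i) / sum_j (1/P_j) and a site's
probability is the sum of w_i over isoforms containing it.

Two isoforms matching identical ion sets therefore split the
probability 0.5/0.5; a single extra matched ion for the best isoform
yields a score strictly between 0.5 and 1; two or more extra ions push
the score towards 1 — the tri-modal structure familiar from
phosphoRS-style scorers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import chem
from .isoforms import ModifiableAlphabet, ALL_PX, PhosphoIsoform, enumerate_isoforms

#: Ion series used per fragmentation type.  EThcD retains b/y through
#: supplemental collisional activation.
SERIES_BY_FRAGMENTATION = {
    "HCD": ("b", "y"),
    "EThcD": ("b", "y", "c", "z"),
}

DEFAULT_TOLERANCE = 0.5   # Da; ion-trap readout
DEFAULT_DEPTH = 8         # peaks retained per 100 m/z window

_TAIL_FLOOR = 1e-300


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 scan."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    fragmentation: str = "HCD"
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    rt_seconds: float | None = None

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        if mz.size and (mz <= 0).any():
            raise ValueError("peak m/z values must be positive")
        if inten.size and (inten < 0).any():
            raise ValueError("peak intensities must be non-negative")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


def filter_peaks(spectrum: Spectrum, depth: int = DEFAULT_DEPTH) -> Spectrum:
    """Retain at most ``depth`` most-intense peaks per 100 m/z window.

    Windows are non-overlapping [100j, 100(j+1)).  Ties at the depth
    boundary are broken in favour of the lower m/z peak.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if spectrum.n_peaks == 0:
        return spectrum
    windows = np.floor(spectrum.mz / 100.0).astype(int)
    keep = np.zeros(spectrum.n_peaks, dtype=bool)
    for w in np.unique(windows):
        idx = np.flatnonzero(windows == w)
        if idx.size <= depth:
            keep[idx] = True
            continue
        # sort by (-intensity, mz): most intense first, lower m/z wins ties
        order = sorted(idx, key=lambda i: (-spectrum.intensity[i], spectrum.mz[i]))
        keep[order[:depth]] = True
    return replace(spectrum, mz=spectrum.mz[keep], intensity=spectrum.intensity[keep])


def match_count(theoretical_mz: Iterable[float], peaks_mz: np.ndarray,
                tolerance: float) -> int:
    """Number of theoretical ions with at least one peak within ±tolerance."""
    peaks = np.asarray(peaks_mz, dtype=float)
    if peaks.size == 0:
        return 0
    count = 0
    for mz in theoretical_mz:
        j = np.searchsorted(peaks, mz)
        near = []
        if j < peaks.size:
            near.append(peaks[j])
        if j > 0:
            near.append(peaks[j - 1])
        if near and min(abs(p - mz) for p in near) <= tolerance:
            count += 1
    return count


@dataclass
class SiteScoreResult:
    """Localisation scores for one PSM."""

    scan_id: str
    sequence: str
    k_phospho: int
    isoform_probabilities: dict[PhosphoIsoform, float]
    site_probabilities: dict[tuple[int, str], float]
    matched_counts: dict[PhosphoIsoform, int]
    n_theoretical: dict[PhosphoIsoform, int]
    rank1_rank2_ion_delta: int
    degenerate: bool = False

    def best_isoform(self) -> PhosphoIsoform:
        return max(self.isoform_probabilities, key=self.isoform_probabilities.get)

    def best_sites(self) -> list[tuple[int, str, float]]:
        """The k top-scoring sites of the best isoform, with probabilities."""
        iso = self.best_isoform()
        return [(p, r, self.site_probabilities[(p, r)]) for p, r in iso.sites()]


def theoretical_ion_mzs(
    isoform: PhosphoIsoform,
    series_set: Sequence[str],
    max_charge: int,
    ignore_neutral_loss: bool = True,
    carbamidomethyl_cys: bool = False,
) -> list[float]:
    ions = chem.fragment_ions(
        isoform, series_set, max_charge,
        include_neutral_losses=not ignore_neutral_loss,
        carbamidomethyl_cys=carbamidomethyl_cys,
    )
    return [ion.mz for ion in ions]


def score_sites(
    spectrum: Spectrum,
    sequence: str,
    k_phospho: int,
    alphabet: ModifiableAlphabet = ALL_PX,
    tolerance: float = DEFAULT_TOLERANCE,
    depth: int = DEFAULT_DEPTH,
    ignore_neutral_loss: bool = True,
    *,
    treat_as_ethcd: bool = False,
    carbamidomethyl_cys: bool = False,
) -> SiteScoreResult:
    """Score all k-phospho isoforms of ``sequence`` against ``spectrum``."""
    if k_phospho < 1:
        raise ValueError("k_phospho must be >= 1 for site localisation")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    isoforms = enumerate_isoforms(sequence, k_phospho, alphabet)
    if not isoforms:
        raise ValueError(f"no modifiable positions in {sequence!r} for this alphabet")

    frag = "EThcD" if treat_as_ethcd else spectrum.fragmentation
    series = SERIES_BY_FRAGMENTATION.get(frag)
    if series is None:
        raise ValueError(f"unknown fragmentation type {frag!r}")
    max_charge = min(2, spectrum.precursor_charge)

    filtered = filter_peaks(spectrum, depth)
    degenerate = filtered.n_peaks == 0

    p = depth * 2.0 * tolerance / 100.0
    p = min(max(p, 1e-12), 0.5)

    matched: dict[PhosphoIsoform, int] = {}
    n_theo: dict[PhosphoIsoform, int] = {}
    inv_tails: list[float] = []
    for iso in isoforms:
        mzs = theoretical_ion_mzs(iso, series, max_charge, ignore_neutral_loss,
                                  carbamidomethyl_cys)
        n_i = len(mzs)
        k_i = match_count(mzs, filtered.mz, tolerance)
        matched[iso] = k_i
        n_theo[iso] = n_i
        tail = max(float(stats.binom.sf(k_i - 1, n_i, p)), _TAIL_FLOOR)
        inv_tails.append(1.0 / tail)

    total = math.fsum(inv_tails)
    weights = [v / total for v in inv_tails]
    iso_probs = dict(zip(isoforms, weights))

    site_probs: dict[tuple[int, str], float] = {}
    for iso, w in iso_probs.items():
        for site in iso.sites():
            site_probs[site] = site_probs.get(site, 0.0) + w

    counts_sorted = sorted(matched.values(), reverse=True)
    delta = counts_sorted[0] - counts_sorted[1] if len(counts_sorted) > 1 else counts_sorted[0]

    return SiteScoreResult(
        scan_id=spectrum.scan_id,
        sequence=sequence,
        k_phospho=k_phospho,
        isoform_probabilities=iso_probs,
        site_probabilities=site_probs,
        matched_counts=matched,
        n_theoretical=n_theo,
        rank1_rank2_ion_delta=delta,
        degenerate=degenerate,
    )


def site_determining_ions(
    isoform_a: PhosphoIsoform,
    isoform_b: PhosphoIsoform,
    series_set: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
    tolerance: float = 1e-6,
) -> tuple[list[chem.FragmentIon], list[chem.FragmentIon]]:
    """Ions unique to each isoform (symmetric difference by m/z)."""
    if isoform_a.sequence != isoform_b.sequence:
        raise ValueError("isoforms must share the same peptide sequence")
    if isoform_a.k != isoform_b.k:
        raise ValueError("isoforms must carry the same number of phospho groups")
    ions_a = chem.fragment_ions(isoform_a, series_set, max_charge)
    ions_b = chem.fragment_ions(isoform_b, series_set, max_charge)
    mz_a = np.array(sorted(i.mz for i in ions_a))
    mz_b = np.array(sorted(i.mz for i in ions_b))

    def _unique(ions, other_mz):
        out = []
        for ion in ions:
            j = np.searchsorted(other_mz, ion.mz)
            near = []
            if j < other_mz.size:
                near.append(other_mz[j])
            if j > 0:
                near.append(other_mz[j - 1])
            if not near or min(abs(m - ion.mz) for m in near) > tolerance:
                out.append(ion)
        return out

    return _unique(ions_a, mz_b), _unique(ions_b, mz_a)
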