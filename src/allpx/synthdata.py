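"""Ground-truth phosphopeptide spectrum simulator.

Random (or supplied) protein sequences are digested with tryptic rules
(cleave after Lys/Arg, never before Pro, up to two missed cleavages);
phosphorylation is planted on the nine modifiable residue classes with
configurable per-class abundance; HCD/EThcD fragment spectra are
emitted with configurable peak-detection probability, noise peaks,
residue-class-specific precursor neutral-loss propensities, planted
identical-ion-set ambiguity and a site-scrambling rate ε for validating
the decoy false-localisation-rate estimator.  Every emitted spectrum
has a ground-truth row; everything is deterministic given the seed.

The intensity model (log-normal fragments, exponential noise) is a
simple seedable stand-in adequate for threshold logic, not a claim of
physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import chem
from .isoforms import (ALL_PX, DECOY_RESIDUE, MAX_MODIFIABLE_DEFAULT,
                       ModifiableAlphabet, PhosphoIsoform, modifiable_positions)
from .localization import SERIES_BY_FRAGMENTATION, Spectrum

#: Human-proteome-like relative residue frequencies for the candidate
#: classes (decoy Ala included), used for sequence generation and for
#: frequency-weighted scrambling.
CLASS_FREQUENCIES = {
    "S": 0.083, "T": 0.054, "Y": 0.027, "H": 0.026, "D": 0.047,
    "E": 0.071, "K": 0.057, "R": 0.056, "C": 0.023, "A": 0.070,
}

#: Residue frequencies used to generate random protein sequences
#: (approximate human proteome composition).
PROTEIN_RESIDUE_FREQUENCIES = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}

#: Per-class precursor neutral-loss propensities (Δ80, Δ98, Δ116),
#: echoing the pattern that hydroxyl-residue phosphopeptides favour
#: phosphoric-acid loss while pHis/pTyr lose HPO3 relatively more often.
NL_PROPENSITIES: dict[str, tuple[float, float, float]] = {
    "S": (0.30, 0.70, 0.67),
    "T": (0.42, 0.70, 0.67),
    "Y": (0.46, 0.45, 0.40),
    "H": (0.51, 0.40, 0.40),
    "D": (0.30, 0.40, 0.40),
    "E": (0.30, 0.40, 0.40),
    "K": (0.30, 0.40, 0.35),
    "R": (0.34, 0.45, 0.54),
    "C": (0.30, 0.40, 0.40),
    "A": (0.30, 0.40, 0.40),
}


def tryptic_digest(protein_sequence: str, max_missed: int = 2) -> list[tuple[str, int, int]]:
    """Tryptic peptides with 0..max_missed missed cleavages.

    Cleaves after K or R except when the next residue is P.  Returns
    (peptide, start position 1-based, n_missed) tuples in N-to-C order.
    """
    seq = protein_sequence
    cut_after = [
        i for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    # fully-cleaved segment boundaries (0-based start, exclusive end)
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i + 1 for i in cut_after] + [len(seq)]
    out = []
    for a in range(len(starts)):
        for miss in range(0, max_missed + 1):
            b = a + miss
            if b >= len(ends):
                break
            out.append((seq[starts[a]:ends[b]], starts[a] + 1, miss))
    return out


def random_proteins(
    rng: np.random.Generator,
    n_proteins: int,
    length: int,
    residue_frequencies: Mapping[str, float] | None = None,
) -> dict[str, str]:
    """Random protein sequences drawn from a residue frequency model."""
    freqs = dict(residue_frequencies or PROTEIN_RESIDUE_FREQUENCIES)
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p = p / p.sum()
    return {
        f"SYN{i:04d}": "".join(rng.choice(letters, size=length, p=p))
        for i in range(n_proteins)
    }


@dataclass
class SimulationConfig:
    """Knobs of the simulator; the seed is mandatory for reproducibility."""

    seed: int
    n_spectra: int = 500
    n_proteins: int = 20
    protein_length: int = 300
    proteins: dict[str, str] | None = None     # overrides random generation
    alphabet: ModifiableAlphabet = ALL_PX
    decoy_active: bool = False                 # swap pCys -> pAla candidates
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(CLASS_FREQUENCIES))
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    max_peptide_length: int = 30
    fragmentation: str = "HCD"
    detection_probability: float = 0.9
    n_noise_peaks: int = 20
    noise_intensity_scale: float = 0.02        # fraction of median fragment intensity
    nl_propensities: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(NL_PROPENSITIES))
    ambiguous_fraction: float = 0.0
    scramble_rate: float = 0.0                 # ε
    fragment_tolerance: float = 0.5

    def __post_init__(self):
        for name in ("detection_probability", "ambiguous_fraction", "scramble_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def active_alphabet(self) -> ModifiableAlphabet:
        return self.alphabet.decoy() if self.decoy_active else self.alphabet


def _eligible_peptides(config: SimulationConfig, proteins: Mapping[str, str],
                       alphabet: ModifiableAlphabet):
    rows = []
    for acc, seq in proteins.items():
        for pep, start, miss in tryptic_digest(seq, config.max_missed_cleavages):
            if not config.min_peptide_length <= len(pep) <= config.max_peptide_length:
                continue
            pos = modifiable_positions(pep, alphabet)
            # respect the downstream enumeration guard on candidate blow-up
            if pos and len(pos) <= MAX_MODIFIABLE_DEFAULT:
                rows.append((acc, pep, start, tuple(pos)))
    return rows


def simulate_spectra(config: SimulationConfig) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate an MS2 corpus with ground truth.

    Returns (spectra, truth).  Truth columns: scan_id, protein, peptide,
    protein_start, true peptide/protein position and residue, emitted
    position and residue, scrambled and ambiguous flags, charge.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = config.active_alphabet()
    proteins = config.proteins or random_proteins(
        rng, config.n_proteins, config.protein_length)
    peptides = _eligible_peptides(config, proteins, alphabet)
    if not peptides:
        raise ValueError("no eligible peptides in the simulated proteome")

    # index peptides by the residue classes they contain
    by_class: dict[str, list[int]] = {}
    for idx, (_, pep, _, positions) in enumerate(peptides):
        for p in positions:
            by_class.setdefault(pep[p - 1], []).append(idx)
    weights = {c: w for c, w in config.class_weights.items() if c in by_class}
    skipped = set(config.class_weights) - set(weights) - {
        c for c in config.class_weights if c not in alphabet.residue_classes}
    if skipped:
        import warnings
        warnings.warn(f"no eligible residues for class(es) {sorted(skipped)}; skipped")
    classes = sorted(weights)
    w = np.array([weights[c] for c in classes], dtype=float)
    w = w / w.sum()

    series = SERIES_BY_FRAGMENTATION[config.fragmentation]
    spectra: list[Spectrum] = []
    truth_rows = []
    for i in range(config.n_spectra):
        scan_id = f"scan_{i:05d}"
        cls = classes[rng.choice(len(classes), p=w)]
        pool = by_class[cls]
        acc, pep, start, positions = peptides[pool[rng.integers(len(pool))]]
        class_positions = [p for p in positions if pep[p - 1] == cls]
        true_pos = int(class_positions[rng.integers(len(class_positions))])

        emitted_pos = true_pos
        scrambled = False
        alternatives = [p for p in positions if p != true_pos]
        if alternatives and rng.random() < config.scramble_rate:
            emitted_pos = int(alternatives[rng.integers(len(alternatives))])
            scrambled = True

        isoform = PhosphoIsoform(pep, frozenset({emitted_pos}))
        charge = int(rng.integers(2, 4))  # 2 or 3
        precursor_mz = (chem.peptide_mass(pep, 1) + charge * chem.PROTON) / charge

        frag_charge = min(2, charge)
        frag_mzs = np.array([ion.mz for ion in
                             chem.fragment_ions(isoform, series, frag_charge)])
        ambiguous = False
        if alternatives and rng.random() < config.ambiguous_fraction:
            # keep only ions shared with the *adjacent* candidate isoform:
            # ions spanning neither or both sites cannot separate the two,
            # and no third candidate lies between them
            ordered = sorted(positions)
            idx = ordered.index(emitted_pos)
            neighbours = [ordered[j] for j in (idx - 1, idx + 1)
                          if 0 <= j < len(ordered)]
            alt_pos = int(neighbours[rng.integers(len(neighbours))])
            alt = PhosphoIsoform(pep, frozenset({alt_pos}))
            alt_mzs = np.sort([ion.mz for ion in
                               chem.fragment_ions(alt, series, frag_charge)])
            j = np.searchsorted(alt_mzs, frag_mzs)
            j = np.clip(j, 0, len(alt_mzs) - 1)
            near = np.minimum(
                np.abs(alt_mzs[j] - frag_mzs),
                np.abs(alt_mzs[np.maximum(j - 1, 0)] - frag_mzs),
            )
            frag_mzs = frag_mzs[near <= 1e-6]
            ambiguous = True

        detected = rng.random(len(frag_mzs)) < config.detection_probability
        mzs = list(frag_mzs[detected])
        intens = list(rng.lognormal(mean=5.0, sigma=1.0, size=len(mzs)))
        base = max(intens) if intens else 1.0

        # precursor neutral-loss peaks per residue-class propensity
        props = config.nl_propensities.get(pep[emitted_pos - 1], (0.0, 0.0, 0.0))
        for delta, prop in zip(chem.NEUTRAL_LOSSES.values(), props):
            if rng.random() < prop:
                mzs.append(precursor_mz - delta / charge)
                intens.append(base * rng.uniform(0.10, 0.60))

        if config.n_noise_peaks:
            median = np.median(intens) if intens else 1.0
            noise_mz = rng.uniform(100.0, max(300.0, precursor_mz * charge), config.n_noise_peaks)
            noise_int = rng.exponential(config.noise_intensity_scale * median,
                                        config.n_noise_peaks)
            mzs.extend(noise_mz)
            intens.extend(noise_int)

        spectra.append(Spectrum(
            scan_id=scan_id,
            precursor_mz=precursor_mz,
            precursor_charge=charge,
            fragmentation=config.fragmentation,
            mz=np.array(mzs), intensity=np.array(intens),
            rt_seconds=float(60 + i),
        ))
        truth_rows.append({
            "scan_id": scan_id,
            "protein": acc,
            "peptide": pep,
            "protein_start": start,
            "true_peptide_position": true_pos,
            "true_protein_position": start + true_pos - 1,
            "true_residue": pep[true_pos - 1],
            "emitted_peptide_position": emitted_pos,
            "emitted_residue": pep[emitted_pos - 1],
            "scrambled": scrambled,
            "ambiguous": ambiguous,
            "charge": charge,
        })
    return spectra, pd.DataFrame(truth_rows)


@dataclass
class SiteCallSimConfig:
    """Fast-path site-call simulator for FLR-estimator validation."""

    seed: int
    n_sites_per_class: int = 500
    scramble_rate: float = 0.2                 # ε
    classes: tuple[str, ...] = ALL_PX.residue_classes
    decoy_residue: str = DECOY_RESIDUE
    class_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(CLASS_FREQUENCIES))
    # tri-modal score mixture: identical-ion-set mass at 0.5, a
    # one-ion-delta mode near 0.85 and a multi-ion-delta mode near 1
    score_mixture: tuple[float, float, float] = (0.25, 0.35, 0.40)


def simulate_sitecalls(
    config: SiteCallSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw site calls with planted mislocalisation.

    True sites are drawn per class; with probability ε a call is
    relabelled to a candidate residue drawn with frequency weighting
    (the decoy residue included — it can only ever receive scrambled
    calls).  Scores come from a tri-modal mixture so that threshold
    logic is exercised identically for true and scrambled calls.

    Returns (site_calls, truth, frequency_table).
    """
    rng = np.random.default_rng(config.seed)
    candidates = [c for c in config.classes if c != config.decoy_residue]
    candidates_with_decoy = candidates + [config.decoy_residue]
    freqs = np.array([config.class_frequencies[c] for c in candidates_with_decoy])
    freqs = freqs / freqs.sum()

    calls, truth = [], []
    counter = 0
    for cls in candidates:
        for _ in range(config.n_sites_per_class):
            counter += 1
            emitted = cls
            scrambled = rng.random() < config.scramble_rate
            if scrambled:
                emitted = candidates_with_decoy[rng.choice(len(freqs), p=freqs)]
            u = rng.random()
            if u < config.score_mixture[0]:
                score = 0.5
            elif u < config.score_mixture[0] + config.score_mixture[1]:
                score = float(np.clip(rng.normal(0.85, 0.04), 0.51, 0.98))
            else:
                score = float(np.clip(1.0 - abs(rng.normal(0.0, 0.005)), 0.99, 1.0))
            protein = f"SIM{counter // 200:04d}"
            position = counter % 200 + 1 + 1000 * (counter // 200 + 1)
            calls.append({
                "protein": protein, "position": position, "residue": emitted,
                "score": score, "c_terminal": False,
            })
            truth.append({
                "protein": protein, "position": position,
                "true_residue": cls, "emitted_residue": emitted,
                "scrambled": scrambled, "score": score,
            })
    freq_table = pd.DataFrame({
        "count": {c: int(round(f * 1e6)) for c, f in
                  zip(candidates_with_decoy, freqs)},
    })
    freq_table["frequency"] = freqs
    freq_table.attrs["basis"] = "configured-class-frequencies"
    return pd.DataFrame(calls), pd.DataFrame(truth), freq_table


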