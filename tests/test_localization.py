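"""Binomial site-localisation scoring.

The oracle used here recomputes everything naively and independently:
explicit subset enumeration, literal fragment-mass sums, O(n·m) peak
matching and an exact binomial tail from math.comb.
"""

import itertools
import math

import numpy as np
import pytest
from pyteomics import mass as pt_mass

from allpx import chem
from allpx.isoforms import ALL_PX, ModifiableAlphabet, PhosphoIsoform
from allpx.localization import (Spectrum, filter_peaks, score_sites,
                                site_determining_ions)

PROTON = 1.00727646688
WATER = 18.0105646863
PHOS = 79.96633089


# ---------------------------------------------------------------- oracle
def _oracle_filter(mzs, intens, depth):
    by_window = {}
    for mz, it in zip(mzs, intens):
        by_window.setdefault(int(mz // 100), []).append((mz, it))
    kept = []
    for w, peaks in by_window.items():
        peaks.sort(key=lambda p: (-p[1], p[0]))
        kept.extend(p[0] for p in peaks[:depth])
    return sorted(kept)


def _oracle_ions(seq, mod_positions, max_charge):
    res = [pt_mass.std_aa_mass[ch] for ch in seq]
    L = len(seq)
    out = []
    for i in range(1, L):
        b = sum(res[:i]) + PHOS * sum(1 for p in mod_positions if p <= i)
        y = sum(res[i:]) + WATER + PHOS * sum(1 for p in mod_positions if p > i)
        for neutral in (b, y):
            for z in range(1, max_charge + 1):
                out.append((neutral + z * PROTON) / z)
    return out


def _oracle_tail(k, n, p):
    return math.fsum(
        math.comb(n, j) * p ** j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def oracle_score(spectrum, seq, k, alphabet_letters, tolerance=0.5, depth=8):
    peaks = _oracle_filter(spectrum.mz, spectrum.intensity, depth)
    positions = [i for i, ch in enumerate(seq, 1) if ch in alphabet_letters]
    max_charge = min(2, spectrum.precursor_charge)
    p = min(max(depth * 2 * tolerance / 100.0, 1e-12), 0.5)
    inv = []
    combos = list(itertools.combinations(positions, k))
    for combo in combos:
        mzs = _oracle_ions(seq, combo, max_charge)
        k_i = sum(1 for mz in mzs if any(abs(mz - q) <= tolerance for q in peaks))
        inv.append(1.0 / max(_oracle_tail(k_i, len(mzs), p), 1e-300))
    total = math.fsum(inv)
    site_probs = {}
    for combo, v in zip(combos, inv):
        for pos in combo:
            key = (pos, seq[pos - 1])
            site_probs[key] = site_probs.get(key, 0.0) + v / total
    return site_probs


# ------------------------------------------------------------ peak filter
class TestFilterPeaks:
    def test_fewer_peaks_than_depth_unchanged(self, make_spectrum):
        s = make_spectrum([110.0, 120.0, 130.0])
        assert filter_peaks(s, 8).n_peaks == 3

    def test_retains_most_intense_per_window(self, make_spectrum):
        mzs = np.linspace(105, 195, 12)
        intens = np.arange(12, dtype=float)
        out = filter_peaks(make_spectrum(mzs, intens), 8)
        assert out.n_peaks == 8
        assert set(out.intensity) == set(range(4, 12))

    def test_tie_break_prefers_lower_mz(self, make_spectrum):
        # two tied peaks compete for the last slot
        mzs = [110.0, 120.0, 130.0]
        intens = [5.0, 5.0, 9.0]
        out = filter_peaks(make_spectrum(mzs, intens), 2)
        assert list(out.mz) == [110.0, 130.0]

    def test_windows_are_independent(self, make_spectrum):
        mzs = [150.0, 250.0, 251.0, 252.0]
        out = filter_peaks(make_spectrum(mzs), 2)
        assert 150.0 in out.mz and out.n_peaks == 3


# ------------------------------------------------------------ score_sites
class TestScoreStructure:
    def test_identical_ion_sets_split_half_half(self, make_spectrum):
        """No site-determining evidence: both candidate sites score exactly 0.5."""
        s = make_spectrum([400.0], precursor_charge=2)  # matches neither isoform
        r = score_sites(s, "SAS", 1, ModifiableAlphabet(("S",)))
        assert r.site_probabilities[(1, "S")] == pytest.approx(0.5, abs=1e-12)
        assert r.site_probabilities[(3, "S")] == pytest.approx(0.5, abs=1e-12)

    def test_full_ladder_localises_above_99(self, make_spectrum):
        iso = PhosphoIsoform("SAYKPK", frozenset({1}))
        mzs = [ion.mz for ion in chem.fragment_ions(iso, ["b", "y"], 2)]
        s = make_spectrum(mzs, precursor_charge=2)
        r = score_sites(s, "SAYKPK", 1)
        assert r.site_probabilities[(1, "S")] > 0.99

    def test_single_ion_delta_strictly_between_half_and_one(self, make_spectrum):
        iso1 = PhosphoIsoform("SAS", frozenset({1}))
        b1 = [i for i in chem.fragment_ions(iso1, ["b"], 1) if i.index == 1]
        s = make_spectrum([b1[0].mz], precursor_charge=1)
        r = score_sites(s, "SAS", 1, ModifiableAlphabet(("S",)))
        p = r.site_probabilities[(1, "S")]
        assert 0.5 < p < 1.0
        assert r.rank1_rank2_ion_delta == 1

    def test_two_ion_delta_above_095(self, make_spectrum):
        iso1 = PhosphoIsoform("SAS", frozenset({1}))
        unique = [i.mz for i in chem.fragment_ions(iso1, ["b"], 1)]
        s = make_spectrum(unique, precursor_charge=1)
        r = score_sites(s, "SAS", 1, ModifiableAlphabet(("S",)))
        assert r.rank1_rank2_ion_delta == 2
        assert r.site_probabilities[(1, "S")] > 0.95

    def test_empty_spectrum_is_degenerate_equiprobable(self, make_spectrum):
        s = make_spectrum([])
        r = score_sites(s, "SAS", 1, ModifiableAlphabet(("S",)))
        assert r.degenerate
        assert r.site_probabilities[(1, "S")] == pytest.approx(0.5, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("seq,k", [("STAYHK", 1), ("STAYHK", 2), ("SDSEK", 2)])
    def test_normalisation(self, make_spectrum, seq, k):
        rng = np.random.default_rng(7)
        s = make_spectrum(rng.uniform(100, 900, 40), rng.uniform(1, 100, 40))
        r = score_sites(s, seq, k)
        assert sum(r.isoform_probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(r.site_probabilities.values()) == pytest.approx(k, abs=1e-9)

    def test_alphabet_order_does_not_change_probabilities(self, make_spectrum):
        rng = np.random.default_rng(11)
        s = make_spectrum(rng.uniform(100, 900, 30))
        a = score_sites(s, "STAYHK", 1, ModifiableAlphabet(("S", "T", "Y", "H", "K")))
        b = score_sites(s, "STAYHK", 1, ModifiableAlphabet(("K", "H", "Y", "T", "S")))
        assert a.site_probabilities == pytest.approx(b.site_probabilities, abs=1e-12)

    def test_adding_isoform_specific_peak_never_decreases_weight(self, make_spectrum):
        rng = np.random.default_rng(3)
        base_mzs = list(rng.uniform(100, 900, 20))
        iso1 = PhosphoIsoform("SAYK", frozenset({1}))
        iso2 = PhosphoIsoform("SAYK", frozenset({3}))
        only1, _ = site_determining_ions(iso1, iso2, ("b", "y"), 1)
        before = score_sites(make_spectrum(base_mzs), "SAYK", 1,
                             ModifiableAlphabet(("S", "Y")))
        after = score_sites(make_spectrum(base_mzs + [only1[0].mz]), "SAYK", 1,
                            ModifiableAlphabet(("S", "Y")))
        assert (after.isoform_probabilities[iso1]
                >= before.isoform_probabilities[iso1] - 1e-12)

    def test_oracle_equivalence_short_peptides(self, make_spectrum):
        """Package probabilities match naive enumeration to 1e-9."""
        rng = np.random.default_rng(42)
        for seq, k in [("SAYK", 1), ("STAYHK", 1), ("STAYHK", 2),
                       ("DECHKR", 1), ("DECHKR", 2), ("SSTTYK", 2)]:
            mzs = rng.uniform(100, 800, 35)
            s = make_spectrum(mzs, rng.uniform(1, 100, 35), precursor_charge=2)
            r = score_sites(s, seq, k)
            expected = oracle_score(s, seq, k, set(ALL_PX.residue_classes))
            assert set(r.site_probabilities) == set(expected)
            for key, val in expected.items():
                assert r.site_probabilities[key] == pytest.approx(val, abs=1e-9)


class TestSiteDeterminingIons:
    def test_identical_isoforms_have_no_unique_ions(self):
        iso = PhosphoIsoform("SAK", frozenset({1}))
        a, b = site_determining_ions(iso, iso)
        assert a == [] and b == []

    def test_terminal_sites_differ_in_flanking_ions(self):
        iso_a = PhosphoIsoform("SAK", frozenset({1}))
        iso_b = PhosphoIsoform("SAK", frozenset({3}))
        a, b = site_determining_ions(iso_a, iso_b, ("b", "y"), 1)
        assert {(i.series, i.index) for i in a} == {("b", 1), ("b", 2),
                                                   ("y", 1), ("y", 2)}
        assert len(a) == len(b) == 4

    def test_different_sequences_rejected(self):
        with pytest.raises(ValueError):
            site_determining_ions(PhosphoIsoform("SAK", frozenset({1})),
                                  PhosphoIsoform("SAR", frozenset({1})))


class TestTrimodalStructure:
    def test_mixed_corpus_reproduces_score_modes(self):
        """Planted ambiguity gives an exact 0.5 mass; well-separated scans
        concentrate near 1 — the tri-modal pattern of binomial scorers."""
        from allpx import synthdata
        cfg = synthdata.SimulationConfig(
            seed=5, n_spectra=150, detection_probability=1.0,
            n_noise_peaks=0, ambiguous_fraction=0.35)
        spectra, truth = synthdata.simulate_spectra(cfg)
        near_half, high, n_amb = 0, 0, 0
        for s, t in zip(spectra, truth.itertuples()):
            r = score_sites(s, t.peptide, 1)
            p = r.site_probabilities[(t.emitted_peptide_position, t.emitted_residue)]
            if t.ambiguous:
                n_amb += 1
                if abs(p - 0.5) <= 0.05:
                    near_half += 1
            elif r.rank1_rank2_ion_delta >= 2 and 0.95 <= p <= 1.0:
                high += 1
        assert n_amb > 20
        # shared-evidence scans pile up around 0.5; separable scans near 1
        assert near_half / n_amb > 0.6
        assert high > 40
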