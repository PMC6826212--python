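"""Precursor neutral-loss triplet scoring and immonium scanning."""

import numpy as np
import pytest

from allpx import chem, nlanalysis
from allpx.localization import Spectrum
from allpx.nlanalysis import (immonium_scan, nl98_trigger, triplet_score,
                              triplet_summary)

D80 = chem.NEUTRAL_LOSSES["HPO3"]
D98 = chem.NEUTRAL_LOSSES["H3PO4"]
D116 = chem.NEUTRAL_LOSSES["H3PO4+H2O"]


def loss_spectrum(make_spectrum, losses, rel_intensities, precursor_mz=600.0,
                  charge=2, extra=()):
    """Spectrum with a 100%-intensity base peak plus chosen loss peaks."""
    mzs = [350.0] + [precursor_mz - d / charge for d in losses] + [m for m, _ in extra]
    intens = [100.0] + [100.0 * r for r in rel_intensities] + [i for _, i in extra]
    return make_spectrum(mzs, intens, precursor_mz=precursor_mz,
                         precursor_charge=charge)


class TestTripletScore:
    def test_all_three_losses_present(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D80, D98, D116], [0.5, 0.5, 0.5])
        assert triplet_score(s).triplet_score == 3

    def test_no_loss_peaks(self, make_spectrum):
        s = make_spectrum([650.0, 700.0], precursor_mz=600.0)
        assert triplet_score(s).triplet_score == 0

    def test_intensity_cutoff_both_sides(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D98], [0.04])
        assert triplet_score(s, cutoff_pct=5.0).triplet_score == 0
        assert triplet_score(s, cutoff_pct=2.0).triplet_score == 1

    def test_cutoff_boundary_inclusive(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D98], [0.05])
        assert triplet_score(s, cutoff_pct=5.0).flags["H3PO4"]

    def test_mass_tolerance_window(self, make_spectrum):
        s = make_spectrum([600.0 - D98 / 2 + 0.6], precursor_mz=600.0)
        assert not triplet_score(s, tolerance=0.5).flags["H3PO4"]
        assert triplet_score(s, tolerance=0.7).flags["H3PO4"]

    def test_lowering_cutoff_never_decreases_score(self, make_spectrum):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 30)
            s = make_spectrum(rng.uniform(100, 900, n), rng.uniform(1, 100, n),
                              precursor_mz=700.0)
            scores = [triplet_score(s, cutoff_pct=c).triplet_score
                      for c in (10.0, 5.0, 2.0)]
            assert scores[0] <= scores[1] <= scores[2]

    def test_permutation_and_high_mass_invariance(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D80, D116], [0.3, 0.3])
        base = triplet_score(s).triplet_score
        perm = np.random.default_rng(1).permutation(s.n_peaks)
        s_perm = make_spectrum(s.mz[perm], s.intensity[perm],
                               precursor_mz=s.precursor_mz,
                               precursor_charge=s.precursor_charge)
        assert triplet_score(s_perm).triplet_score == base
        # adding peaks above the precursor (below base-peak intensity)
        s_extra = make_spectrum(list(s.mz) + [650.0, 800.0],
                                list(s.intensity) + [50.0, 50.0],
                                precursor_mz=s.precursor_mz,
                                precursor_charge=s.precursor_charge)
        assert triplet_score(s_extra).triplet_score == base

    def test_linear_scan_oracle(self, make_spectrum):
        """Naive O(peaks x 3) scan agrees with the searchsorted implementation."""
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = rng.integers(1, 25)
            mzs = rng.uniform(100, 900, n)
            intens = rng.uniform(1, 100, n)
            pre = rng.uniform(400, 900)
            z = int(rng.integers(1, 4))
            s = make_spectrum(mzs, intens, precursor_mz=pre, precursor_charge=z)
            cutoff = float(rng.choice([2.0, 5.0, 10.0]))
            expected = 0
            min_int = intens.max() * cutoff / 100.0
            for delta in (D80, D98, D116):
                target = pre - delta / z
                if any(abs(m - target) <= 0.5 and it >= min_int
                       for m, it in zip(mzs, intens)):
                    expected += 1
            assert triplet_score(s, 0.5, cutoff).triplet_score == expected

    def test_missing_charge_requires_singly_mode(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D98], [0.5], charge=1)
        assert triplet_score(s, charge_mode="singly").flags["H3PO4"]


class TestNL98Trigger:
    def test_trigger_on_98(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D98], [0.5])
        assert nl98_trigger(s)

    def test_no_trigger_on_80_only(self, make_spectrum):
        s = loss_spectrum(make_spectrum, [D80], [0.5])
        assert not nl98_trigger(s)


class TestImmoniumScan:
    def test_phosphotyrosine_detected(self, make_spectrum):
        s = make_spectrum([500.0, 216.04], [100.0, 10.0])
        r = immonium_scan(s, ["Y", "H"])
        assert r.flags == {"Y": True, "H": False}

    def test_empty_spectrum_all_false(self, make_spectrum):
        r = immonium_scan(make_spectrum([]), ["Y", "H", "K"])
        assert not any(r.flags.values())

    def test_outside_tolerance_window(self, make_spectrum):
        s = make_spectrum([500.0, 216.8], [100.0, 50.0])
        assert not immonium_scan(s, ["Y"], tolerance=0.5).flags["Y"]

    def test_relative_intensity_threshold(self, make_spectrum):
        s = make_spectrum([500.0, 190.04], [100.0, 3.0])
        assert not immonium_scan(s, ["H"], min_rel_intensity=5.0).flags["H"]
        assert immonium_scan(s, ["H"], min_rel_intensity=2.0).flags["H"]


class TestTripletSummary:
    def test_all_zero_scores(self, make_spectrum):
        results = [triplet_score(make_spectrum([650.0], precursor_mz=600.0,
                                               scan_id=f"s{i}"))
                   for i in range(5)]
        score_pct, combos = triplet_summary(results, {f"s{i}": "S" for i in range(5)})
        assert score_pct.loc["S", "score_0_pct"] == 100.0

    def test_rows_sum_to_hundred(self, make_spectrum):
        rng = np.random.default_rng(2)
        results, residues = [], {}
        for i in range(60):
            losses = [d for d in (D80, D98, D116) if rng.random() < 0.5]
            s = loss_spectrum(make_spectrum, losses, [0.5] * len(losses))
            s = Spectrum(f"s{i}", s.precursor_mz, s.precursor_charge,
                         s.fragmentation, s.mz, s.intensity)
            results.append(triplet_score(s))
            residues[f"s{i}"] = rng.choice(["S", "H", "D"])
        score_pct, _ = triplet_summary(results, residues)
        assert np.allclose(score_pct.sum(axis=1), 100.0, atol=0.01)

    def test_independent_propensities_product(self, make_spectrum):
        """With independent per-loss propensity 0.7, the score-3 fraction
        approaches 0.343 (binomial product), checked within 3 sigma."""
        rng = np.random.default_rng(8)
        n = 1000
        n3 = 0
        for _ in range(n):
            losses = [d for d in (D80, D98, D116) if rng.random() < 0.7]
            s = loss_spectrum(make_spectrum, losses, [0.5] * len(losses))
            n3 += triplet_score(s).triplet_score == 3
        expected = 0.7 ** 3
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(n3 / n - expected) < 3 * se

    def test_empty_join_warns(self, make_spectrum):
        results = [triplet_score(make_spectrum([650.0], precursor_mz=600.0))]
        with pytest.warns(UserWarning):
            score_pct, combos = triplet_summary(results, {})
        assert score_pct.empty
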