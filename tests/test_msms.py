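"""Fragment masses, peak matching, shift localization and occupancy."""

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight
from hypothesis import given
from hypothesis import strategies as st

from asphkit import msms
from asphkit.msms import (
    HYDROXYLATION_DELTA,
    PROTON,
    BasePeptideNotDetected,
    FragmentIon,
    LocalizationError,
    Modification,
    OccupancyUndefinedError,
    Peptide,
    SpectrumMatch,
    estimate_occupancy,
    localize_from_spectrum,
    localize_shift,
    match_peaks,
    monoisotopic_mass,
    theoretical_by_ions,
)

from conftest import random_protein

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=25)


def oracle_mass(sequence: str, mod_positions=()) -> float:
    """Independent peptide mass via Biopython's monoisotopic molecular weight."""
    m = molecular_weight(sequence, seq_type="protein", monoisotopic=True)
    return m + len(mod_positions) * HYDROXYLATION_DELTA


class TestMonoisotopicMass:
    def test_glycine(self):
        assert monoisotopic_mass(Peptide("G")) == pytest.approx(75.03203, abs=1e-5)

    def test_hydroxylation_adds_exactly_one_oxygen(self):
        base = Peptide("ACDEFGHIK")
        mod = Peptide("ACDEFGHIK", (Modification(3),))
        delta = monoisotopic_mass(mod) - monoisotopic_mass(base)
        assert delta == pytest.approx(15.994915, abs=1e-9)
        assert round(delta) == 16

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            Peptide("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            Peptide("ACBDE")

    @given(peptides)
    def test_agrees_with_biopython_oracle(self, seq):
        # the two mass tables differ in the 7th decimal per residue
        assert monoisotopic_mass(Peptide(seq)) == pytest.approx(
            oracle_mass(seq), abs=1e-4
        )


class TestFragmentIons:
    @given(peptides, st.integers(min_value=0, max_value=30))
    def test_sum_rule(self, seq, mod_offset):
        """b_i + y_{n-i} = M + 2*proton for singly charged ions, any peptide,
        with or without a modification."""
        n = len(seq)
        mods = (Modification(mod_offset % n + 1),) if mod_offset else ()
        pep = Peptide(seq, mods)
        ions = theoretical_by_ions(pep, max_charge=1)
        b = {f.index: f.mz for f in ions if f.series == "b"}
        y = {f.index: f.mz for f in ions if f.series == "y"}
        total = monoisotopic_mass(pep) + 2 * PROTON
        for i in range(1, n):
            assert b[i] + y[n - i] == pytest.approx(total, abs=1e-6)

    def test_shift_span_logic(self):
        """A modification at position 6 of a 12-mer shifts y_i for i >= 7 and
        b_i for i >= 6, and no other ion."""
        seq = "ACDEFGHIKLMN"
        plain = {(f.series, f.index): f.mz for f in theoretical_by_ions(Peptide(seq))}
        mod = {
            (f.series, f.index): f.mz
            for f in theoretical_by_ions(Peptide(seq, (Modification(6),)))
        }
        for (series, i), mz in mod.items():
            shifted = mz - plain[(series, i)]
            expect = (
                HYDROXYLATION_DELTA
                if (series == "b" and i >= 6) or (series == "y" and i >= 7)
                else 0.0
            )
            assert shifted == pytest.approx(expect, abs=1e-9)

    def test_cumulative_sum_oracle(self, rng):
        """Fragment m/z agree with an independent suffix/prefix-sum oracle
        (same residue masses, independent span bookkeeping)."""
        from pyteomics.mass import std_aa_mass

        water = 18.0105646863
        for _ in range(25):
            seq = random_protein(rng, int(rng.integers(5, 20)))
            pos = int(rng.integers(1, len(seq) + 1))
            pep = Peptide(seq, (Modification(pos),))
            residue_sum = lambda s: sum(std_aa_mass[a] for a in s)
            for f in theoretical_by_ions(pep, max_charge=2):
                if f.series == "b":
                    neutral = residue_sum(seq[: f.index])
                    if pos <= f.index:
                        neutral += HYDROXYLATION_DELTA
                else:
                    neutral = residue_sum(seq[len(seq) - f.index:]) + water
                    if pos > len(seq) - f.index:
                        neutral += HYDROXYLATION_DELTA
                assert f.mz == pytest.approx(
                    (neutral + f.charge * PROTON) / f.charge, abs=1e-6
                )

    def test_charge_and_length_preconditions(self):
        with pytest.raises(ValueError):
            theoretical_by_ions(Peptide("ACD"), max_charge=0)
        with pytest.raises(ValueError):
            theoretical_by_ions(Peptide("A"))


class TestMatchPeaks:
    def test_exact_peaks_all_matched(self):
        pep = Peptide("ACDEFGHIK")
        ions = theoretical_by_ions(pep)
        peaks = [(f.mz, 100.0) for f in ions]
        m = match_peaks(peaks, ions, tol_ppm=10, peptide=pep)
        assert len(m.matched) == len(ions)
        assert all(pm.ppm_error == 0.0 for pm in m.matched)

    def test_displaced_peaks_unmatched(self):
        pep = Peptide("ACDEFGHIK")
        ions = theoretical_by_ions(pep)
        peaks = [(f.mz * (1 + 20e-6), 100.0) for f in ions]  # 2x tolerance
        m = match_peaks(peaks, ions, tol_ppm=10, peptide=pep)
        assert m.matched == ()
        assert len(m.unmatched_theoretical) == len(ions)

    def test_empty_peak_list(self):
        pep = Peptide("ACD")
        ions = theoretical_by_ions(pep)
        m = match_peaks([], ions, tol_ppm=10, peptide=pep)
        assert m.matched == () and len(m.unmatched_theoretical) == len(ions)

    def test_one_peak_serves_one_ion(self):
        ions = [FragmentIon("b", 1, 1, 100.0), FragmentIon("y", 2, 1, 100.0001)]
        m = match_peaks([(100.0, 50.0)], ions, tol_ppm=10)
        assert len(m.matched) == 1
        assert m.matched[0].ion.series == "b"  # closest ppm wins


class TestLocalizeShift:
    def _match(self, seq, keys):
        ions = tuple(
            FragmentIon(s, i, 1, 100.0 + i) for s, i in keys
        )
        matches = tuple(msms.PeakMatch(f, f.mz, 0.0) for f in ions)
        return SpectrumMatch(Peptide(seq), matches, ())

    def test_y7_and_up_shifted_gives_position_6(self):
        seq = "ACDEFGHIKLMN"  # n = 12
        unshifted = self._match(seq, [("y", i) for i in range(1, 7)])
        shifted = self._match(seq, [("y", i) for i in range(7, 12)])
        assert localize_shift(unshifted, shifted) == (6, 6)

    def test_nterminal_boundary_site(self):
        # site at position 1: every b ion shifted, every y ion unshifted
        seq = "ACDEFGHIKLMN"
        unshifted = self._match(seq, [("y", i) for i in range(1, 12)])
        shifted = self._match(seq, [("b", i) for i in range(1, 12)])
        assert localize_shift(unshifted, shifted) == (1, 1)

    def test_partial_series_gives_interval(self):
        seq = "ACDEFGHIKLMN"
        unshifted = self._match(seq, [("y", i) for i in range(1, 4)])  # site <= 9
        shifted = self._match(seq, [("y", 11)])  # site >= 2
        assert localize_shift(unshifted, shifted) == (2, 9)

    def test_contradictory_ion_raises(self):
        seq = "ACDEFGHIKLMN"
        unshifted = self._match(seq, [("y", 8)])
        shifted = self._match(seq, [("y", 8)])
        with pytest.raises(LocalizationError, match="both"):
            localize_shift(unshifted, shifted)

    def test_empty_interval_raises(self):
        seq = "ACDEFGHIKLMN"
        unshifted = self._match(seq, [("b", 8)])  # site >= 9
        shifted = self._match(seq, [("b", 3)])  # site <= 3
        with pytest.raises(LocalizationError):
            localize_shift(unshifted, shifted)

    def test_complete_series_localizes_uniquely(self, rng):
        for _ in range(20):
            seq = random_protein(rng, int(rng.integers(6, 16)))
            site = int(rng.integers(1, len(seq) + 1))
            pep = Peptide(seq, (Modification(site),))
            peaks = [(f.mz, 100.0) for f in theoretical_by_ions(pep)]
            (lo, hi), _ = localize_from_spectrum(seq, peaks)
            assert lo == hi == site


class TestOccupancy:
    @pytest.mark.parametrize(
        "ih,ib,expected",
        [(5.0, 0.0, 100.0), (0.0, 8.0, 0.0), (3.0, 7.0, 30.0)],
    )
    def test_ratio(self, ih, ib, expected):
        assert estimate_occupancy(ih, ib).percent == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(OccupancyUndefinedError):
            estimate_occupancy(0.0, 0.0)

    def test_base_not_detected(self):
        with pytest.raises(BasePeptideNotDetected):
            estimate_occupancy(5.0, None)

    @given(
        st.floats(min_value=0.0, max_value=1e9),
        st.floats(min_value=1e-6, max_value=1e9),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_scale_invariance(self, ih, ib, scale):
        base = estimate_occupancy(ih, ib).percent
        scaled = estimate_occupancy(ih * scale, ib * scale).percent
        assert scaled == pytest.approx(base, abs=1e-9)
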