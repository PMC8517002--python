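"""Spectral library parsing, theoretical fragment masses, pseudo shifts."""

import numpy as np
import pytest
from pyteomics import mass as pmass

from diaxic import chem, speclib
from diaxic.speclib import (
    LibraryFormatError,
    PseudoModParams,
    apply_pseudo_modification_shift,
    parse_library,
    theoretical_fragment_mzs,
    write_library,
)

HEADER = (
    "PrecursorMz\tProductMz\tLibraryIntensity\tNormalizedRetentionTime\t"
    "PeptideSequence\tFullUniModPeptideName\tPrecursorCharge\tProductCharge\t"
    "FragmentType\tFragmentSeriesNumber\tProteinName\tdecoy"
)


def _tsv(tmp_path, rows, header=HEADER):
    p = tmp_path / "lib.tsv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


def _row(seq="PEPTIDER", pmz=478.74, z=2, frag="y4", fmz=500.0, inten=100.0,
         nrt=42.0, protein="P1", decoy=0):
    return (f"{pmz}\t{fmz}\t{inten}\t{nrt}\t{seq}\t{seq}\t{z}\t1\t"
            f"{frag[0]}\t{frag[1:]}\t{protein}\t{decoy}")


class TestParseLibrary:
    def test_groups_fragments_under_precursors(self, tmp_path):
        rows = [_row(frag=f"y{i}", fmz=400.0 + i) for i in (3, 4, 5)]
        rows += [_row(seq="ELVISLIVESK", pmz=600.3, frag=f"b{i}", fmz=300.0 + i)
                 for i in (2, 3, 4)]
        entries = parse_library(_tsv(tmp_path, rows))
        assert len(entries) == 2
        assert all(len(e.fragments) == 3 for e in entries)
        assert entries[0].modified_sequence == "PEPTIDER"
        assert entries[1].protein_id == "P1"

    def test_missing_column_is_named(self, tmp_path):
        header = HEADER.replace("ProductMz\t", "")
        rows = ["\t".join(_row().split("\t")[:1] + _row().split("\t")[2:])]
        with pytest.raises(LibraryFormatError, match="ProductMz"):
            parse_library(_tsv(tmp_path, rows, header=header))

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(LibraryFormatError, match="no transitions"):
            parse_library(_tsv(tmp_path, []))

    def test_no_topn_filtering_at_parse_time(self, tmp_path):
        rows = [_row(frag=f"y{i}", fmz=300.0 + i) for i in range(2, 27)]
        (entry,) = parse_library(_tsv(tmp_path, rows))
        assert len(entry.fragments) == 25

    def test_write_read_round_trip(self, tmp_path):
        rows = [_row(frag=f"y{i}", fmz=400.0 + i, inten=10.0 * i)
                for i in (3, 4, 5)]
        entries = parse_library(_tsv(tmp_path, rows))
        out = tmp_path / "out.tsv"
        write_library(entries, out)
        again = parse_library(out)
        assert len(again) == len(entries)
        for a, b in zip(entries, again):
            assert a.modified_sequence == b.modified_sequence
            assert a.precursor_mz == b.precursor_mz
            assert a.normalized_rt == b.normalized_rt
            assert a.is_decoy == b.is_decoy
            for fa, fb in zip(a.fragments, b.fragments):
                assert (fa.annotation, fa.charge) == (fb.annotation, fb.charge)
                assert fa.mz == fb.mz
                assert fa.library_intensity == fb.library_intensity


class TestTheoreticalFragments:
    @pytest.mark.parametrize("seq,charge,expected", [
        ("ACDEFGHK", 3, 28),   # 2 series x 7 positions x 2 charges
        ("ACDEFGHK", 2, 14),
        ("PEPTIDE", 2, 12),
    ])
    def test_ion_count(self, seq, charge, expected):
        assert len(theoretical_fragment_mzs(seq, charge)) == expected

    def test_b2_of_peptide_matches_reference_calculator(self):
        ions = dict(
            ((a, q), m) for a, q, m in theoretical_fragment_mzs("PEPTIDE", 2)
        )
        assert ions[("b2", 1)] == pytest.approx(227.1026, abs=1e-4)
        # cross-check the whole b/y series against pyteomics
        for (ann, q), mz in ions.items():
            series, idx = ann[0], int(ann[1:])
            sub = "PEPTIDE"[:idx] if series == "b" else "PEPTIDE"[-idx:]
            ref = pmass.fast_mass(sub, ion_type=series, charge=q)
            assert mz == pytest.approx(ref, abs=2e-3)

    def test_complementary_ions_conserve_precursor_mass(self):
        seq = "LNQPEPTIDESK"
        total = chem.peptide_neutral_mass(seq)
        ions = dict(
            ((a, q), m) for a, q, m in theoretical_fragment_mzs(seq, 2)
        )
        for i in range(1, len(seq)):
            b = chem.mz_to_neutral_mass(ions[(f"b{i}", 1)], 1)
            y = chem.mz_to_neutral_mass(ions[(f"y{len(seq) - i}", 1)], 1)
            assert b + y == pytest.approx(total, abs=1e-4)

    def test_charge_rule_follows_precursor_charge(self):
        charges = {q for _, q, _ in theoretical_fragment_mzs("ACDEFGHK", 2)}
        assert charges == {1}
        charges = {q for _, q, _ in theoretical_fragment_mzs("ACDEFGHK", 4)}
        assert charges == {1, 2}

    def test_modified_residue_shifts_covering_fragments_only(self):
        plain = dict(
            ((a, q), m) for a, q, m in theoretical_fragment_mzs("ANCDEK", 2)
        )
        mod = dict(
            ((a, q), m)
            for a, q, m in theoretical_fragment_mzs("AN(UniMod:7)CDEK", 2)
        )
        delta = chem.DEAMIDATION_SHIFT
        assert mod[("b1", 1)] == pytest.approx(plain[("b1", 1)], abs=1e-9)
        assert mod[("b2", 1)] == pytest.approx(plain[("b2", 1)] + delta, abs=1e-6)
        assert mod[("y4", 1)] == pytest.approx(plain[("y4", 1)], abs=1e-9)
        assert mod[("y5", 1)] == pytest.approx(plain[("y5", 1)] + delta, abs=1e-6)

    def test_unknown_token_is_named(self):
        with pytest.raises(chem.UnknownResidueError, match="UniMod:99"):
            theoretical_fragment_mzs("PEPTC(UniMod:99)K", 2)
        with pytest.raises(chem.UnknownResidueError):
            theoretical_fragment_mzs("PEPT1DE", 2)


class TestPseudoModificationShift:
    @pytest.mark.parametrize("n,c,expected", [
        (0, 1, 500.0),
        (1, 1, 500.0387),
        (2, 2, 500.0387),   # N/C cancellation
    ])
    def test_shift_arithmetic(self, n, c, expected):
        out = apply_pseudo_modification_shift(
            500.0, PseudoModParams(n_mods=n, ion_charge=c)
        )
        assert out == pytest.approx(expected, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PseudoModParams(n_mods=-1, ion_charge=1)
        with pytest.raises(ValueError):
            PseudoModParams(n_mods=1, ion_charge=0)

    def test_deamidation_shift_from_element_masses(self):
        # replacing NH by O on an Asn/Gln side chain
        delta = (pmass.calculate_mass(formula="O")
                 - pmass.calculate_mass(formula="NH"))
        assert round(delta, 4) == 0.9840
        assert chem.DEAMIDATION_SHIFT == pytest.approx(delta, abs=1e-5)

    def test_pseudo_library_shifts_only_deamidated_entries(self):
        from diaxic.speclib import FragmentIon, LibraryEntry, make_pseudo_shift_library

        plain = LibraryEntry("PEPTIDEK", 450.0, 2, 10.0,
                             [FragmentIon("y3", 375.2, 1, 5.0)], "P1")
        deam = LibraryEntry("PEN(UniMod:7)TIDEK", 460.0, 2, 12.0,
                            [FragmentIon("y6", 690.0, 1, 5.0),
                             FragmentIon("y2", 260.0, 1, 2.0)], "P2")
        out = make_pseudo_shift_library([plain, deam])
        assert out[0].fragments[0].mz == 375.2
        assert out[0].precursor_mz == 450.0
        # y6 covers the deamidated residue; y2 does not
        assert out[1].fragments[0].mz == pytest.approx(690.0 + 0.0387, abs=1e-6)
        assert out[1].fragments[1].mz == 260.0
        assert out[1].precursor_mz == pytest.approx(460.0 + 0.0387 / 2, abs=1e-6)
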