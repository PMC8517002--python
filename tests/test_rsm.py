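"""RSM assembly: layout, sorting, zero-filling, normalization."""

import numpy as np
import pytest

from diaxic import rsm as rsm_mod
from diaxic.rsm import (
    RSMParams, assemble_rsm, assemble_windows, extract_precursor_traces,
    normalize_matrices, normalize_rsm, pearson,
)
from diaxic.speclib import FragmentIon, LibraryEntry


class TestPearson:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_reversed_ramp(self):
        assert pearson(np.array([1, 2, 3]), np.array([3, 2, 1])) == pytest.approx(-1.0)

    def test_zero_variance_convention(self):
        assert pearson(np.zeros(5), np.arange(5.0)) == 0.0
        assert pearson(np.full(5, 3.0), np.arange(5.0)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson(np.zeros(3), np.zeros(4))


class TestParams:
    def test_default_layout_is_170_rows(self):
        p = RSMParams()
        assert p.n_rows == 170
        assert [s for _, s in p.part_layout] == [20, 20, 20, 50, 10, 10, 20, 20]

    @pytest.mark.parametrize("excluded,expected", [
        ({"light"}, 150),
        ({"light", "iso"}, 130),
        ({"light", "iso", "qt3"}, 120),
        ({"light", "iso", "qt3", "ms1"}, 110),
        ({"light", "iso", "qt3", "ms1", "self"}, 60),
        ({"light", "iso", "qt3", "ms1", "self", "library_045r"}, 40),
        ({"light", "iso", "qt3", "ms1", "self", "library_045r", "library_02r"}, 20),
    ])
    def test_ablation_row_counts(self, excluded, expected):
        assert RSMParams(excluded_parts=frozenset(excluded)).n_rows == expected

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RSMParams(n_cycles=2)
        with pytest.raises(ValueError):
            RSMParams(excluded_parts=frozenset({"nope"}))


def _first_present(exp):
    idx = exp.truth.index[exp.truth.present][0]
    return exp.library[idx], int(exp.truth.apex_cycle[idx])


class TestAssembly:
    def test_default_shape_and_blocks(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        r = assemble_rsm(tiny_exp.run, entry, apex)
        assert r.matrix.shape == (170, 12)
        assert r.part("self").shape == (50, 12)
        assert r.part("ms1").shape == (10, 12)
        assert np.all(r.matrix >= 0)

    def test_zero_filling_beyond_available_fragments(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        n = len(entry.fragments)   # generator makes 6..15 fragments
        r = assemble_rsm(tiny_exp.run, entry, apex)
        for part in ("library_r", "library_02r", "library_045r", "iso", "light"):
            assert np.all(r.part(part)[n:] == 0)

    def test_ms1_qt3_padding_rows_are_zero(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        r = assemble_rsm(tiny_exp.run, entry, apex)
        assert np.all(r.part("ms1")[8:] == 0)   # 8 enumerated MS1 traces
        assert np.all(r.part("qt3")[5:] == 0)   # 5 enumerated MS2 traces

    def test_excluded_parts_shrink_matrix(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        p = RSMParams(excluded_parts=frozenset({"light", "iso"}))
        r = assemble_rsm(tiny_exp.run, entry, apex, p)
        assert r.matrix.shape == (130, 12)
        with pytest.raises(KeyError):
            r.part("light")

    def test_library_sorting_is_a_permutation_with_max_first(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        params = RSMParams()
        traces = extract_precursor_traces(tiny_exp.run, entry, params)
        r = assemble_rsm(tiny_exp.run, entry, apex, params)
        lib = r.part("library_r")
        # permutation: same multiset of rows as the unsorted window slice
        raw = rsm_mod._slice_windows(traces.lib_r, np.array([apex]), params)[0]
        assert sorted(map(tuple, lib)) == sorted(map(tuple, raw))
        # first row attains the maximal correlation sum
        def corr_sum(i, rows):
            return sum(pearson(rows[i], rows[j])
                       for j in range(len(rows)) if j != i)
        sums = [corr_sum(i, lib) for i in range(len(lib))]
        assert corr_sum(0, lib) == pytest.approx(max(sums), abs=1e-9)

    def test_iso_light_and_resolutions_track_library_order(self, tiny_exp):
        """Row i of every library-aligned block refers to the fragment of
        library@r row i."""
        entry, apex = _first_present(tiny_exp)
        params = RSMParams()
        traces = extract_precursor_traces(tiny_exp.run, entry, params)
        aw = assemble_windows(traces, [apex], params)
        order = aw.lib_order[0]
        r = assemble_rsm(tiny_exp.run, entry, apex, params)
        for name, block in (("library_02r", traces.lib_02),
                            ("library_045r", traces.lib_045),
                            ("iso", traces.iso), ("light", traces.light)):
            raw = rsm_mod._slice_windows(block, np.array([apex]), params)[0]
            assert np.allclose(r.part(name), raw[order])

    def test_self_rows_sorted_by_corr_with_first_library_row(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        r = assemble_rsm(tiny_exp.run, entry, apex)
        first = r.part("library_r")[0]
        cors = [pearson(row, first) for row in r.part("self")]
        assert all(a >= b - 1e-9 for a, b in zip(cors, cors[1:]))

    def test_edge_window_zero_padded(self, tiny_exp):
        entry, _ = _first_present(tiny_exp)
        r = assemble_rsm(tiny_exp.run, entry, 0)
        assert r.matrix.shape == (170, 12)
        left_cols = RSMParams().center_offset
        assert np.all(r.matrix[:, :left_cols] == 0)

    def test_apex_appears_at_center_column(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        r = assemble_rsm(tiny_exp.run, entry, apex)
        row = r.part("library_r")[0]
        assert abs(int(np.argmax(row)) - RSMParams().center_offset) <= 1


class TestNormalization:
    def test_scaling_by_global_max(self, rng):
        m = rng.random((170, 12)) * 200.0
        out = normalize_matrices(m)
        assert out.max() == pytest.approx(1.0)
        assert np.allclose(out, m / m.max())

    def test_all_zero_unchanged(self):
        z = np.zeros((170, 12))
        assert np.all(normalize_matrices(z) == 0)

    def test_idempotent(self, rng):
        m = rng.random((10, 12))
        once = normalize_matrices(m)
        assert np.allclose(normalize_matrices(once), once)

    def test_rsm_wrapper(self, tiny_exp):
        entry, apex = _first_present(tiny_exp)
        r = normalize_rsm(assemble_rsm(tiny_exp.run, entry, apex))
        assert 0.0 <= r.matrix.min() and r.matrix.max() == pytest.approx(1.0)


def test_entry_without_fragments_is_impossible():
    with pytest.raises(ValueError, match="no fragments"):
        LibraryEntry("PEPK", 400.0, 2, 1.0, [], "P1")


def test_batched_extraction_equals_per_entry(tiny_exp):
    from diaxic.rsm import extract_traces_for_entries

    entries = tiny_exp.library[:5]
    params = RSMParams()
    batched = extract_traces_for_entries(tiny_exp.run, entries, params)
    for e, tr in zip(entries, batched):
        solo = extract_precursor_traces(tiny_exp.run, e, params)
        for name in ("lib_r", "lib_02", "lib_045", "self_", "qt3", "ms1",
                     "iso", "light"):
            assert np.allclose(getattr(tr, name), getattr(solo, name)), name
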