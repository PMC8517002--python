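"""Representative spectral matrices (RSMs).

An RSM bundles, for one precursor at one candidate RT location, a fixed
window (default 12 acquisition cycles) of extracted ion chromatograms in six
named blocks, 170 rows under defaults:

==============  ====  =======================================================
block           rows  contents
==============  ====  =======================================================
library@r        20   top-20 library fragments by library intensity, at the
                      basic resolution r, sorted by the sum of Pearson
                      correlations with the other library rows
library@0.2r     20   same fragments, narrower window, same row order
library@0.45r    20   same fragments, narrower window, same row order
self             50   all theoretical b/y ions (charge 1 for precursor
                      charge <= 2, else charges 1 and 2), intensity-filtered
                      or zero-filled to 50, sorted by correlation with the
                      first library@r row
qt3              10   unfragmented precursor and its (M+1)/q..(M+4)/q
                      isotopes extracted from MS2 spectra (zero-padded)
ms1              10   precursor at r, 0.2r, 0.45r plus (M+1)/q..(M+4)/q and
                      (M-1)/q isotopologues from MS1 spectra (zero-padded)
iso              20   (M+1)/q trace of each library fragment, library order
light            20   (M-1)/q trace of each library fragment, library order
==============  ====  =======================================================

Blocks can be excluded for ablation experiments, shrinking the row count.
Zero-variance rows take Pearson correlation 0 by convention; all sorts are
stable with descending key, so ties keep their original order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import chem, speclib
from .raw_io import RunData, extract_traces
from .speclib import LibraryEntry

__all__ = [
    "PART_ORDER", "PART_SIZES", "RSMParams", "RSM", "PrecursorTraces",
    "pearson", "extract_precursor_traces", "assemble_windows",
    "assemble_rsm", "normalize_rsm",
]

PART_ORDER: tuple[str, ...] = (
    "library_r", "library_02r", "library_045r",
    "self", "qt3", "ms1", "iso", "light",
)

PART_SIZES: dict[str, int] = {
    "library_r": 20, "library_02r": 20, "library_045r": 20,
    "self": 50, "qt3": 10, "ms1": 10, "iso": 20, "light": 20,
}

#: resolution multipliers of the two narrower library extraction windows
NARROW_FACTORS = (0.2, 0.45)


@dataclass(frozen=True)
class RSMParams:
    """Extraction/assembly parameters of the RSM."""

    basic_resolution: float = 30.0       # r
    resolution_unit: str = "ppm"         # "ppm" | "Da"
    n_cycles: int = 12
    excluded_parts: frozenset = frozenset()

    def __post_init__(self):
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")
        if self.resolution_unit not in ("ppm", "Da"):
            raise ValueError("resolution_unit must be 'ppm' or 'Da'")
        bad = set(self.excluded_parts) - set(PART_ORDER)
        if bad:
            raise ValueError(f"unknown part name(s) in excluded_parts: {sorted(bad)}")
        object.__setattr__(self, "excluded_parts", frozenset(self.excluded_parts))

    @property
    def part_layout(self) -> list[tuple[str, int]]:
        """Ordered (name, rows) blocks actually present."""
        return [(p, PART_SIZES[p]) for p in PART_ORDER
                if p not in self.excluded_parts]

    @property
    def n_rows(self) -> int:
        return sum(size for _, size in self.part_layout)

    @property
    def center_offset(self) -> int:
        """Column index of the window center (candidate apex)."""
        return (self.n_cycles - 1) // 2


@dataclass
class RSM:
    """One assembled matrix with its layout metadata."""

    matrix: np.ndarray                     # [n_rows, n_cycles]
    part_layout: list[tuple[str, int]]
    center_cycle: int
    precursor_ref: LibraryEntry
    params: RSMParams
    library_fragments: list | None = None  # fragments in final library-row order

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def part(self, name: str) -> np.ndarray:
        """View of one named block of rows."""
        row = 0
        for p, size in self.part_layout:
            if p == name:
                return self.matrix[row:row + size]
            row += size
        raise KeyError(f"part {name!r} not present in this RSM")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention.

    Returns 0.0 when either input is constant (e.g. an all-zero zero-filled
    XIC row), so degenerate rows sort deterministically.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    # constancy checked by value, not by computed variance: the mean of n
    # identical floats can round away from them, faking a tiny variance
    if x.max() == x.min() or y.max() == y.min():
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


# ---------------------------------------------------------------------------
# full-gradient trace extraction


@dataclass
class PrecursorTraces:
    """Full-gradient raw XIC traces of one precursor, pre-window layout.

    Library-derived arrays are zero-filled to the fixed block sizes already;
    the self block keeps its natural ion count (filtered per window later).
    """

    entry: LibraryEntry
    lib_r: np.ndarray      # [20, T]
    lib_02: np.ndarray     # [20, T]
    lib_045: np.ndarray    # [20, T]
    self_: np.ndarray      # [n_theoretical, T]
    qt3: np.ndarray        # [5, T]
    ms1: np.ndarray        # [8, T]
    iso: np.ndarray        # [20, T]
    light: np.ndarray      # [20, T]
    lib_fragments: list    # top library fragments (pre-sort order), len <= 20


def _top_library_fragments(entry: LibraryEntry, k: int = 20) -> list:
    order = sorted(
        range(len(entry.fragments)),
        key=lambda i: (-entry.fragments[i].library_intensity, i),
    )
    return [entry.fragments[i] for i in order[:k]]


def _entry_ms2_queries(entry: LibraryEntry, params: RSMParams):
    """All MS2-level target m/z values and tolerances for one precursor.

    Returns (mzs, tolerances, slices) where slices maps block names to row
    ranges in the stacked query array.
    """
    r = params.basic_resolution
    frags = _top_library_fragments(entry)
    fmz = np.array([f.mz for f in frags])
    fq = np.array([f.charge for f in frags])
    theo = speclib.theoretical_fragment_mzs(
        entry.modified_sequence, entry.precursor_charge
    )
    self_mz = np.array([mz for _, _, mz in theo])
    pmz, z = entry.precursor_mz, entry.precursor_charge
    qt3_mz = np.array([chem.isotope_mz(pmz, z, k) for k in range(5)])

    mzs, tols, slices = [], [], {}
    pos = 0

    def add(name, arr, tol):
        nonlocal pos
        mzs.append(arr)
        tols.append(np.full(arr.shape, tol))
        slices[name] = slice(pos, pos + arr.size)
        pos += arr.size

    add("lib_r", fmz, r)
    add("lib_02", fmz, NARROW_FACTORS[0] * r)
    add("lib_045", fmz, NARROW_FACTORS[1] * r)
    add("self", self_mz, r)
    add("qt3", qt3_mz, r)
    add("iso", fmz + chem.ISOTOPE_SPACING / fq, r)
    add("light", fmz - chem.ISOTOPE_SPACING / fq, r)
    return np.concatenate(mzs), np.concatenate(tols), slices, frags


def _entry_ms1_queries(entry: LibraryEntry, params: RSMParams):
    """MS1-level queries: precursor at 3 resolutions, M+1..M+4 and M-1 at r."""
    r = params.basic_resolution
    pmz, z = entry.precursor_mz, entry.precursor_charge
    mzs = np.array(
        [pmz, pmz, pmz]
        + [chem.isotope_mz(pmz, z, k) for k in (1, 2, 3, 4, -1)]
    )
    tols = np.array([r, NARROW_FACTORS[0] * r, NARROW_FACTORS[1] * r]
                    + [r] * 5)
    return mzs, tols


def _pad_rows(arr: np.ndarray, n: int) -> np.ndarray:
    if arr.shape[0] >= n:
        return arr[:n]
    out = np.zeros((n, arr.shape[1]), dtype=arr.dtype)
    out[:arr.shape[0]] = arr
    return out


def extract_precursor_traces(
    run: RunData, entry: LibraryEntry, params: RSMParams
) -> PrecursorTraces:
    """Extract every full-gradient trace the RSM of this precursor needs."""
    if not entry.fragments:
        raise ValueError("entry has no library fragments")
    widx = run.window_index_for_mz(entry.precursor_mz)
    mzs, tols, slices, frags = _entry_ms2_queries(entry, params)
    ms2_traces = extract_traces(
        run, mzs, tols, params.resolution_unit, "ms2", window_index=widx
    )
    ms1_mzs, ms1_tols = _entry_ms1_queries(entry, params)
    ms1_traces = extract_traces(
        run, ms1_mzs, ms1_tols, params.resolution_unit, "ms1"
    )
    return PrecursorTraces(
        entry=entry,
        lib_r=_pad_rows(ms2_traces[slices["lib_r"]], 20),
        lib_02=_pad_rows(ms2_traces[slices["lib_02"]], 20),
        lib_045=_pad_rows(ms2_traces[slices["lib_045"]], 20),
        self_=ms2_traces[slices["self"]],
        qt3=ms2_traces[slices["qt3"]],
        ms1=ms1_traces,
        iso=_pad_rows(ms2_traces[slices["iso"]], 20),
        light=_pad_rows(ms2_traces[slices["light"]], 20),
        lib_fragments=frags,
    )


def extract_traces_for_entries(
    run: RunData, entries: list[LibraryEntry], params: RSMParams
) -> list[PrecursorTraces]:
    """Batched variant of :func:`extract_precursor_traces`.

    Entries sharing an isolation window are extracted in one pass over the
    run, which is substantially faster than per-entry extraction; results
    are identical.
    """
    by_window: dict[int, list[int]] = {}
    for i, e in enumerate(entries):
        by_window.setdefault(run.window_index_for_mz(e.precursor_mz), []).append(i)

    out: list[PrecursorTraces | None] = [None] * len(entries)
    ms1_queries, ms1_tols, ms1_owner = [], [], []
    for widx, idxs in by_window.items():
        all_mz, all_tol, metas = [], [], []
        pos = 0
        for i in idxs:
            mzs, tols, slices, frags = _entry_ms2_queries(entries[i], params)
            all_mz.append(mzs)
            all_tol.append(tols)
            metas.append((i, pos, slices, frags))
            pos += mzs.size
        stacked = extract_traces(
            run, np.concatenate(all_mz), np.concatenate(all_tol),
            params.resolution_unit, "ms2", window_index=widx,
        )
        for i, offset, slices, frags in metas:
            def blk(name):
                s = slices[name]
                return stacked[offset + s.start: offset + s.stop]
            out[i] = PrecursorTraces(
                entry=entries[i],
                lib_r=_pad_rows(blk("lib_r"), 20),
                lib_02=_pad_rows(blk("lib_02"), 20),
                lib_045=_pad_rows(blk("lib_045"), 20),
                self_=blk("self"),
                qt3=blk("qt3"),
                ms1=np.empty((0, run.n_cycles)),  # filled below
                iso=_pad_rows(blk("iso"), 20),
                light=_pad_rows(blk("light"), 20),
                lib_fragments=frags,
            )
        for i in idxs:
            mzs, tols = _entry_ms1_queries(entries[i], params)
            ms1_queries.append(mzs)
            ms1_tols.append(tols)
            ms1_owner.append(i)

    ms1_stacked = extract_traces(
        run, np.concatenate(ms1_queries), np.concatenate(ms1_tols),
        params.resolution_unit, "ms1",
    )
    pos = 0
    for i, q in zip(ms1_owner, ms1_queries):
        out[i].ms1 = ms1_stacked[pos:pos + q.size]
        pos += q.size
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# windowed assembly


def _slice_windows(arr: np.ndarray, centers: np.ndarray, params: RSMParams):
    """[k, T] traces -> [n_win, k, n_cycles] windows, zero-padded at edges."""
    T = arr.shape[1]
    left = params.center_offset
    cols = centers[:, None] - left + np.arange(params.n_cycles)[None, :]
    valid = (cols >= 0) & (cols < T)
    gathered = arr[:, np.clip(cols, 0, T - 1)]          # [k, n_win, n_c]
    gathered = np.where(valid[None, :, :], gathered, 0.0)
    return np.ascontiguousarray(np.moveaxis(gathered, 0, 1))  # [n_win, k, n_c]


def _batched_corr(x: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations per window; zero-variance rows -> 0.

    x: [n_win, k, n_c] -> [n_win, k, k]
    """
    xc = x - x.mean(axis=2, keepdims=True)
    norms = np.sqrt(np.einsum("wkc,wkc->wk", xc, xc))
    constant = x.max(axis=2) == x.min(axis=2)
    norms = np.where(constant, 0.0, norms)
    corr = np.einsum("wic,wjc->wij", xc, xc)
    denom = norms[:, :, None] * norms[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, corr / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(corr, -1.0, 1.0), norms


def _corr_with_row(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson of each row of x with a reference row, per window.

    x: [n_win, k, n_c], ref: [n_win, n_c] -> [n_win, k]
    """
    xc = x - x.mean(axis=2, keepdims=True)
    rc = ref - ref.mean(axis=1, keepdims=True)
    nx = np.sqrt(np.einsum("wkc,wkc->wk", xc, xc))
    nx = np.where(x.max(axis=2) == x.min(axis=2), 0.0, nx)
    nr = np.sqrt(np.einsum("wc,wc->w", rc, rc))
    nr = np.where(ref.max(axis=1) == ref.min(axis=1), 0.0, nr)
    num = np.einsum("wkc,wc->wk", xc, rc)
    denom = nx * nr[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(out, -1.0, 1.0)


def _take_rows(x: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Reorder rows per window: x [n_win, k, n_c], order [n_win, k']."""
    return np.take_along_axis(
        x, order[:, :, None].repeat(x.shape[2], axis=2), axis=1
    )


@dataclass
class AssembledWindows:
    """RSMs assembled at many candidate centers of one precursor."""

    entry: LibraryEntry
    centers: np.ndarray            # [n_win] cycle indices
    matrices: np.ndarray           # [n_win, n_rows, n_cycles], unnormalized
    lib_block: np.ndarray          # [n_win, 20, n_cycles] sorted library@r rows
    lib_order: np.ndarray          # [n_win, 20] original-row permutation
    params: RSMParams

    @property
    def lib_sum(self) -> np.ndarray:
        return self.lib_block.sum(axis=(1, 2))

    @property
    def lib_nonzero_rows(self) -> np.ndarray:
        return (self.lib_block.sum(axis=2) > 0).sum(axis=1)


def assemble_windows(
    traces: PrecursorTraces, centers, params: RSMParams
) -> AssembledWindows:
    """Assemble (unnormalized) RSMs at every requested center cycle."""
    centers = np.atleast_1d(np.asarray(centers, dtype=np.int64))

    lib_r = _slice_windows(traces.lib_r, centers, params)
    corr, norms = _batched_corr(lib_r)
    # sum of correlations with the *other* rows: drop the self term (1 for
    # rows with signal, 0 for degenerate rows)
    corr_sums = corr.sum(axis=2) - (norms > 0).astype(np.float64)
    corr_sums = np.where(norms > 0, corr_sums, 0.0)
    order = np.argsort(-corr_sums, axis=1, kind="stable")

    lib_r_sorted = _take_rows(lib_r, order)
    first_lib = lib_r_sorted[:, 0, :]

    blocks: dict[str, np.ndarray] = {}
    blocks["library_r"] = lib_r_sorted
    blocks["library_02r"] = _take_rows(_slice_windows(traces.lib_02, centers, params), order)
    blocks["library_045r"] = _take_rows(_slice_windows(traces.lib_045, centers, params), order)

    if "self" not in params.excluded_parts:
        s = _slice_windows(traces.self_, centers, params)
        k_target = PART_SIZES["self"]
        if s.shape[1] > k_target:
            # intensity filter: keep the 50 most intense ions in this window
            sums = s.sum(axis=2)
            keep = np.argsort(-sums, axis=1, kind="stable")[:, :k_target]
            s = _take_rows(s, keep)
        sc = _corr_with_row(s, first_lib)
        s = _take_rows(s, np.argsort(-sc, axis=1, kind="stable"))
        if s.shape[1] < k_target:
            pad = np.zeros((s.shape[0], k_target - s.shape[1], s.shape[2]))
            s = np.concatenate([s, pad], axis=1)
        blocks["self"] = s

    if "qt3" not in params.excluded_parts:
        q = _slice_windows(traces.qt3, centers, params)
        pad = np.zeros((q.shape[0], PART_SIZES["qt3"] - q.shape[1], q.shape[2]))
        blocks["qt3"] = np.concatenate([q, pad], axis=1)

    if "ms1" not in params.excluded_parts:
        m = _slice_windows(traces.ms1, centers, params)
        pad = np.zeros((m.shape[0], PART_SIZES["ms1"] - m.shape[1], m.shape[2]))
        blocks["ms1"] = np.concatenate([m, pad], axis=1)

    if "iso" not in params.excluded_parts:
        blocks["iso"] = _take_rows(_slice_windows(traces.iso, centers, params), order)
    if "light" not in params.excluded_parts:
        blocks["light"] = _take_rows(_slice_windows(traces.light, centers, params), order)

    matrices = np.concatenate(
        [blocks[p] for p, _ in params.part_layout], axis=1
    )
    return AssembledWindows(
        entry=traces.entry,
        centers=centers,
        matrices=matrices,
        lib_block=lib_r_sorted,
        lib_order=order,
        params=params,
    )


def assemble_rsm(
    run: RunData,
    entry: LibraryEntry,
    center_cycle: int,
    params: RSMParams | None = None,
) -> RSM:
    """Assemble one (unnormalized) RSM for a precursor at a candidate cycle."""
    params = params or RSMParams()
    traces = extract_precursor_traces(run, entry, params)
    aw = assemble_windows(traces, [center_cycle], params)
    frag_by_orig = {i: f for i, f in enumerate(traces.lib_fragments)}
    lib_frags = [frag_by_orig.get(int(j)) for j in aw.lib_order[0]]
    return RSM(
        matrix=aw.matrices[0],
        part_layout=params.part_layout,
        center_cycle=center_cycle,
        precursor_ref=entry,
        params=params,
        library_fragments=lib_frags,
    )


def normalize_matrices(matrices: np.ndarray) -> np.ndarray:
    """Global-max scaling per RSM; all-zero matrices pass through unchanged."""
    m = np.asarray(matrices, dtype=np.float64)
    if m.ndim == 2:
        peak = m.max()
        return m / peak if peak > 0 else m.copy()
    peaks = m.max(axis=(1, 2), keepdims=True)
    return m / np.where(peaks > 0, peaks, 1.0)


def normalize_rsm(rsm: RSM) -> RSM:
    """Model-input conditioning: divide by the matrix's global maximum."""
    return replace(rsm, matrix=normalize_matrices(rsm.matrix))
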