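"""Cycle-indexed access to centroided DIA runs and XIC extraction.

A DIA run is a sequence of acquisition cycles, each holding one MS1 survey
spectrum followed by one MS2 spectrum per precursor isolation window. Both
mzML and mzXML are read (via pyteomics); spectra must be centroided.

Extraction sums all centroid peaks inside the m/z tolerance window of the
target, per cycle. Internally each spectrum keeps its m/z array sorted with
a prefix-sum of intensities so a window sum is two binary searches; the
result is contractually identical to a linear scan over the peak list.
"""

from __future__ import annotations

import base64
import gzip
import zlib
from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from pyteomics import mzxml as _mzxml


class RunFormatError(ValueError):
    pass


@dataclass
class Spectrum:
    """A centroided spectrum with sorted m/z and an intensity prefix sum."""

    mz: np.ndarray
    intensity: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        order = np.argsort(self.mz, kind="stable")
        self.mz = np.asarray(self.mz, dtype=np.float64)[order]
        self.intensity = np.asarray(self.intensity, dtype=np.float64)[order]
        self._cum = np.concatenate(([0.0], np.cumsum(self.intensity)))

    def window_sums(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Summed intensity inside [lo_i, hi_i] for each query window."""
        i0 = np.searchsorted(self.mz, lo, side="left")
        i1 = np.searchsorted(self.mz, hi, side="right")
        return self._cum[i1] - self._cum[i0]

    @property
    def total_intensity(self) -> float:
        return float(self._cum[-1])


_EMPTY = None


def _empty_spectrum() -> Spectrum:
    global _EMPTY
    if _EMPTY is None:
        _EMPTY = Spectrum(np.empty(0), np.empty(0))
    return _EMPTY


@dataclass
class RunData:
    """One DIA run: RT-ordered cycles of MS1 + isolation-windowed MS2 spectra."""

    rt_per_cycle: np.ndarray                  # seconds, strictly increasing
    isolation_windows: np.ndarray             # [W, 2] low/high m/z
    ms1: list[Spectrum]                       # one per cycle
    ms2: list[list[Spectrum | None]]          # [cycle][window]

    def __post_init__(self):
        self.rt_per_cycle = np.asarray(self.rt_per_cycle, dtype=np.float64)
        if np.any(np.diff(self.rt_per_cycle) <= 0):
            raise RunFormatError("cycle retention times must be strictly increasing")
        self.isolation_windows = np.asarray(self.isolation_windows, dtype=np.float64)

    @property
    def n_cycles(self) -> int:
        return len(self.rt_per_cycle)

    @property
    def cycle_spacing_s(self) -> float:
        return float(np.median(np.diff(self.rt_per_cycle)))

    def window_index_for_mz(self, mz: float) -> int:
        """Isolation window containing mz; overlaps resolved to the nearest
        window center."""
        w = self.isolation_windows
        inside = np.flatnonzero((w[:, 0] <= mz) & (mz <= w[:, 1]))
        if inside.size == 0:
            raise ValueError(
                f"precursor m/z {mz:.4f} falls outside every isolation window"
            )
        centers = w[inside].mean(axis=1)
        return int(inside[np.argmin(np.abs(centers - mz))])

    def ms2_spectrum(self, cycle: int, window: int) -> Spectrum:
        s = self.ms2[cycle][window]
        return s if s is not None else _empty_spectrum()


@dataclass
class XIC:
    """Intensity-per-cycle trace of one target m/z."""

    values: np.ndarray
    target_mz: float
    tolerance: float
    unit: str                 # "ppm" | "Da"
    level: str                # "ms1" | "ms2"


def tolerance_bounds(
    mzs: np.ndarray, tolerance: float, unit: str
) -> tuple[np.ndarray, np.ndarray]:
    mzs = np.asarray(mzs, dtype=np.float64)
    if unit == "ppm":
        half = mzs * tolerance * 1e-6
    elif unit == "Da":
        half = np.full_like(mzs, tolerance)
    else:
        raise ValueError(f"unit must be 'ppm' or 'Da', got {unit!r}")
    return mzs - half, mzs + half


def extract_traces(
    run: RunData,
    mzs: np.ndarray,
    tolerance,
    unit: str,
    level: str,
    window_index: int | None = None,
    cycle_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """XICs for many target m/z values at once -> [n_targets, n_cycles].

    ``tolerance`` may be a scalar or a per-target array (same unit for all).
    """
    mzs = np.atleast_1d(np.asarray(mzs, dtype=np.float64))
    if np.isscalar(tolerance) or np.ndim(tolerance) == 0:
        lo, hi = tolerance_bounds(mzs, float(tolerance), unit)
    else:
        tol = np.asarray(tolerance, dtype=np.float64)
        if unit == "ppm":
            half = mzs * tol * 1e-6
        else:
            half = tol
        lo, hi = mzs - half, mzs + half

    c0, c1 = cycle_range if cycle_range is not None else (0, run.n_cycles)
    c0 = max(c0, 0)
    c1 = min(c1, run.n_cycles)
    out = np.zeros((mzs.size, max(c1 - c0, 0)), dtype=np.float64)
    for j, cyc in enumerate(range(c0, c1)):
        if level == "ms1":
            spec = run.ms1[cyc]
        else:
            assert window_index is not None, "MS2 extraction needs a window index"
            spec = run.ms2_spectrum(cyc, window_index)
        if spec.mz.size:
            out[:, j] = spec.window_sums(lo, hi)
    return out


def extract_xic(
    run: RunData,
    target_mz: float,
    tolerance: float,
    unit: str = "ppm",
    level: str = "ms2",
    window_mz: float | None = None,
    cycle_range: tuple[int, int] | None = None,
) -> XIC:
    """Extract one XIC; MS2 traces are read from the isolation window that
    contains ``window_mz`` (the precursor m/z)."""
    widx = None
    if level == "ms2":
        if window_mz is None:
            raise ValueError("MS2 extraction requires window_mz (precursor m/z)")
        widx = run.window_index_for_mz(window_mz)
    values = extract_traces(
        run, np.array([target_mz]), tolerance, unit, level, widx, cycle_range
    )[0]
    return XIC(values=values, target_mz=target_mz, tolerance=tolerance,
               unit=unit, level=level)


# ---------------------------------------------------------------------------
# file readers


def _dedupe_windows(raw: list[tuple[float, float]]) -> np.ndarray:
    uniq = sorted({(round(lo, 4), round(hi, 4)) for lo, hi in raw})
    return np.array(uniq, dtype=np.float64)


def _finalize(cycles, windows_raw) -> RunData:
    if not cycles:
        raise RunFormatError("no MS1 spectra found; not a cycle-structured DIA file")
    if not any(c["ms2"] for c in cycles):
        raise RunFormatError("no MS2 spectra found; not a DIA file")
    windows = _dedupe_windows(windows_raw)
    wkey = {(round(lo, 4), round(hi, 4)): i for i, (lo, hi) in enumerate(windows)}
    rt = np.array([c["rt"] for c in cycles])
    ms1 = [c["ms1"] for c in cycles]
    ms2: list[list[Spectrum | None]] = []
    for c in cycles:
        row: list[Spectrum | None] = [None] * len(windows)
        for (lo, hi), spec in c["ms2"]:
            row[wkey[(round(lo, 4), round(hi, 4))]] = spec
        ms2.append(row)
    return RunData(rt_per_cycle=rt, isolation_windows=windows, ms1=ms1, ms2=ms2)


def _open_source(path):
    p = str(path)
    return gzip.open(p, "rb") if p.endswith(".gz") else p


def _decode_binary(b64_text: str, accessions: set[str]) -> np.ndarray:
    raw = base64.b64decode(b64_text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = np.float32 if "MS:1000521" in accessions else np.float64
    return np.frombuffer(raw, dtype=dtype)


def _load_mzml(path) -> RunData:
    """Minimal namespace-agnostic mzML 1.1 reader (centroided spectra only).

    Understands the cvParams this package needs: ms level, centroid/profile
    flags, scan start time (minute or second units), isolation window
    target/offsets, 32/64-bit float arrays, zlib or no compression.
    """
    cycles: list[dict] = []
    windows_raw: list[tuple[float, float]] = []
    source = _open_source(path)
    for _, elem in etree.iterparse(source, events=("end",),
                                   tag="{*}spectrum"):
        cv = {
            p.get("accession"): p.get("value", "")
            for p in elem.iter("{*}cvParam")
        }
        if "MS:1000128" in cv:
            raise RunFormatError(
                "profile-mode spectra found; centroid the data first"
            )
        level = int(cv.get("MS:1000511", "1"))
        arrays = {}
        for bda in elem.iter("{*}binaryDataArray"):
            acc = {p.get("accession") for p in bda.iter("{*}cvParam")}
            node = bda.find("{*}binary")
            data = _decode_binary(node.text or "", acc)
            if "MS:1000514" in acc:
                arrays["mz"] = data
            elif "MS:1000515" in acc:
                arrays["intensity"] = data
        spec = Spectrum(arrays.get("mz", np.empty(0)),
                        arrays.get("intensity", np.empty(0)))
        if level == 1:
            rt_s = None
            for scan in elem.iter("{*}scan"):
                for p in scan.iter("{*}cvParam"):
                    if p.get("accession") == "MS:1000016":
                        rt_s = float(p.get("value"))
                        if str(p.get("unitName", "second")).startswith("min"):
                            rt_s *= 60.0
            if rt_s is None:
                raise RunFormatError("MS1 spectrum without a scan start time")
            cycles.append({"rt": rt_s, "ms1": spec, "ms2": []})
        else:
            if not cycles:
                raise RunFormatError("MS2 spectrum before the first MS1 scan")
            iso = elem.find("{*}precursorList/{*}precursor/{*}isolationWindow")
            if iso is None:
                raise RunFormatError("MS2 spectrum without an isolation window")
            icv = {p.get("accession"): float(p.get("value"))
                   for p in iso.iter("{*}cvParam")}
            center = icv["MS:1000827"]
            lo = center - icv.get("MS:1000828", 0.0)
            hi = center + icv.get("MS:1000829", 0.0)
            windows_raw.append((lo, hi))
            cycles[-1]["ms2"].append(((lo, hi), spec))
        elem.clear()
    if hasattr(source, "close"):
        source.close()
    return _finalize(cycles, windows_raw)


def _load_mzxml(path) -> RunData:
    cycles: list[dict] = []
    windows_raw: list[tuple[float, float]] = []
    with _mzxml.read(_open_source(path)) as reader:
        for sp in reader:
            if int(sp.get("centroided", 1)) == 0:
                raise RunFormatError(
                    "profile-mode spectra found; centroid the data first"
                )
            level = int(sp["msLevel"])
            spec = Spectrum(sp["m/z array"], sp["intensity array"])
            rt_s = float(sp["retentionTime"]) * 60.0  # mzXML RT is in minutes
            if level == 1:
                cycles.append({"rt": rt_s, "ms1": spec, "ms2": []})
            else:
                if not cycles:
                    raise RunFormatError("MS2 spectrum before the first MS1 scan")
                prec = sp["precursorMz"][0]
                center = float(prec["precursorMz"])
                width = float(prec.get("windowWideness", 25.0))
                lo, hi = center - width / 2.0, center + width / 2.0
                windows_raw.append((lo, hi))
                cycles[-1]["ms2"].append(((lo, hi), spec))
    return _finalize(cycles, windows_raw)


def load_run(path) -> RunData:
    """Load a centroided mzML/mzXML DIA run into cycle-indexed form."""
    p = str(path)
    base = p[:-3] if p.endswith(".gz") else p
    if base.lower().endswith(".mzml"):
        return _load_mzml(p)
    if base.lower().endswith(".mzxml"):
        return _load_mzxml(p)
    raise RunFormatError(f"unrecognized raw file extension: {p}")
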