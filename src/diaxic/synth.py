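"""Synthetic DIA experiments with known ground truth.

The generator emulates the structure every downstream module assumes: a
cycle-structured run (one MS1 survey plus one MS2 spectrum per isolation
window, ~3 s per cycle), Gaussian elution peaks whose apexes follow a known
linear library-RT -> run-RT map, fragment peak heights proportional to
library intensities, MS1 isotope envelopes, fragment M+1 isotopes,
co-eluting interference peptides, a Poisson noise floor, and a configurable
fraction of library precursors entirely absent from the sample. Peaks are
emitted as centroids at theoretical m/z with 2 ppm Gaussian jitter.

What it deliberately does not model: detector saturation, profile peak
shapes, charge-state cross-talk, tailing/fronting elution, or ion mobility.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem, speclib
from .raw_io import RunData, Spectrum
from .speclib import FragmentIon, LibraryEntry

__all__ = [
    "SynthConfig", "SynthExperiment", "generate_experiment",
    "generate_rsm_training_set", "write_mzml", "write_mzxml",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a synthetic DIA experiment."""

    n_precursors: int = 1000
    fraction_present: float = 1.0
    rt_map: tuple[float, float] = (2.0, 30.0)    # seconds = slope*nrt + intercept
    normalized_rt_range: tuple[float, float] = (0.0, 100.0)
    peak_width_s: float = 6.0                    # Gaussian sigma
    cycle_time_s: float = 3.0
    n_cycles_total: int = 100
    window_range: tuple[float, float] = (400.0, 1200.0)
    n_windows: int = 64
    noise_floor: float = 5.0                     # mean noise-peak intensity
    noise_peaks_per_spectrum: float = 30.0       # Poisson mean
    interference_rate: float = 0.1
    isotope_model: tuple[float, ...] = (1.0, 0.8, 0.4, 0.15, 0.05)
    fragment_isotope_ratio: float = 0.5          # M+1 height vs monoisotopic
    mz_jitter_ppm: float = 2.0
    abundance_median: float = 500.0
    abundance_sigma: float = 0.8                 # lognormal sigma (ln units)
    condition_ratios: tuple[float, ...] | None = None
    deamidated_fraction: float = 0.0
    min_length: int = 7
    max_length: int = 20
    min_fragments: int = 6
    max_fragments: int = 15
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_present", "interference_rate", "deamidated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peak_width_s <= 0 or self.cycle_time_s <= 0:
            raise ValueError("widths and cycle time must be > 0")


@dataclass
class SynthExperiment:
    """Generated library + run + per-precursor ground truth."""

    library: list[LibraryEntry]
    run: RunData
    truth: pd.DataFrame            # sequence, charge, present, apex_s, apex_cycle,
    config: SynthConfig            # abundance, group, ratio


def _random_peptide(rng, cfg: SynthConfig, deamidated: bool) -> str:
    L = int(rng.integers(cfg.min_length, cfg.max_length + 1))
    seq = [_AA[i] for i in rng.integers(0, len(_AA), L - 1)]
    seq.append("K" if rng.random() < 0.5 else "R")
    if deamidated:
        pos = int(rng.integers(1, L - 1))
        seq[pos] = "N(UniMod:7)"
    return "".join(seq)


def _make_entry(rng, cfg: SynthConfig, index: int, deamidated: bool) -> LibraryEntry | None:
    seq = _random_peptide(rng, cfg, deamidated)
    charge = 2 if rng.random() < 0.7 else 3
    pmz = chem.precursor_mz(seq, charge)
    lo, hi = cfg.window_range
    if not (lo < pmz < hi):
        return None
    theo = [
        (ann, q, mz)
        for ann, q, mz in speclib.theoretical_fragment_mzs(seq, charge)
        if q == 1 and 150.0 < mz < 1800.0 and int(ann[1:]) >= 2
    ]
    if len(theo) < cfg.min_fragments:
        return None
    n_frag = int(rng.integers(cfg.min_fragments,
                              min(cfg.max_fragments, len(theo)) + 1))
    picked = rng.choice(len(theo), size=n_frag, replace=False)
    rel = np.exp(rng.normal(0.0, 1.0, n_frag))
    rel /= rel.max()
    frags = [
        FragmentIon(theo[i][0], theo[i][2], theo[i][1], float(w))
        for i, w in zip(sorted(picked), rel)
    ]
    nrt = float(rng.uniform(*cfg.normalized_rt_range))
    return LibraryEntry(
        modified_sequence=seq,
        precursor_mz=pmz,
        precursor_charge=charge,
        normalized_rt=nrt,
        fragments=frags,
        protein_id=f"PROT_{index // 3}",   # ~3 precursors per synthetic protein
        is_decoy=False,
    )


def make_library(cfg: SynthConfig, rng=None) -> list[LibraryEntry]:
    """Random tryptic-like spectral library under the config's conditions."""
    rng = rng or np.random.default_rng(cfg.seed)
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    n_deamid = round(cfg.deamidated_fraction * cfg.n_precursors)
    attempts = 0
    while len(entries) < cfg.n_precursors and attempts < 100 * cfg.n_precursors:
        attempts += 1
        e = _make_entry(rng, cfg, len(entries), len(entries) < n_deamid)
        if e is not None and e.modified_sequence not in seen:
            seen.add(e.modified_sequence)
            entries.append(e)
    if len(entries) < cfg.n_precursors:
        raise RuntimeError("could not generate the requested library size")
    return entries


def _isolation_windows(cfg: SynthConfig) -> np.ndarray:
    edges = np.linspace(*cfg.window_range, cfg.n_windows + 1)
    return np.column_stack([edges[:-1], edges[1:]])


def generate_experiment(
    cfg: SynthConfig,
    condition: int = 0,
    present_mask: np.ndarray | None = None,
    library: list[LibraryEntry] | None = None,
) -> SynthExperiment:
    """Build the library (unless given), the centroided run and ground truth.

    ``condition`` selects the abundance column in two-condition mode (the
    library, apexes and presence pattern are shared across conditions; only
    abundances change by the per-group ratio). ``present_mask`` overrides the
    seeded presence draw, e.g. to mark a spiked-in foreign species absent.
    """
    rng = np.random.default_rng(cfg.seed)
    entries = library if library is not None else make_library(cfg, rng)
    n = len(entries)
    windows = _isolation_windows(cfg)
    rt = (np.arange(cfg.n_cycles_total) + 1.0) * cfg.cycle_time_s

    if present_mask is None:
        n_present = round(cfg.fraction_present * n)
        present = np.zeros(n, dtype=bool)
        present[rng.choice(n, size=n_present, replace=False)] = True
    else:
        present = np.asarray(present_mask, dtype=bool).copy()
        if present.shape != (n,):
            raise ValueError("present_mask length must match the library")

    slope, intercept = cfg.rt_map
    nrts = np.array([e.normalized_rt for e in entries])
    apex_s = slope * nrts + intercept
    apex_cycle = np.abs(rt[None, :] - apex_s[:, None]).argmin(axis=1)
    sigma = cfg.peak_width_s * rng.uniform(0.8, 1.2, n)   # +-20% width jitter
    base_abund = cfg.abundance_median * np.exp(
        rng.normal(0.0, cfg.abundance_sigma, n)
    )
    if cfg.condition_ratios is not None:
        groups = np.arange(n) % len(cfg.condition_ratios)
        ratios = np.asarray(cfg.condition_ratios)[groups]
    else:
        groups = np.zeros(n, dtype=int)
        ratios = np.ones(n)
    abund = base_abund * np.where(condition == 0, 1.0, ratios)

    # peak buckets: (mz, intensity) accumulated per spectrum
    ms1_mz = [[] for _ in range(cfg.n_cycles_total)]
    ms1_int = [[] for _ in range(cfg.n_cycles_total)]
    ms2_mz = [[[] for _ in range(cfg.n_windows)] for _ in range(cfg.n_cycles_total)]
    ms2_int = [[[] for _ in range(cfg.n_windows)] for _ in range(cfg.n_cycles_total)]

    def window_of(mz: float) -> int | None:
        i = int(np.searchsorted(windows[:, 1], mz))
        if i >= len(windows) or not windows[i, 0] <= mz <= windows[i, 1]:
            return None
        return i

    def emit(pmz, z, frag_mz, frag_h, a, mu, sg, widx):
        """Emit one eluting species into the peak buckets."""
        c0 = max(int(np.searchsorted(rt, mu - 4 * sg)), 0)
        c1 = min(int(np.searchsorted(rt, mu + 4 * sg)), cfg.n_cycles_total)
        if c0 >= c1:
            return
        g = a * np.exp(-0.5 * ((rt[c0:c1] - mu) / sg) ** 2)
        iso = np.asarray(cfg.isotope_model)
        iso_mz = np.array([chem.isotope_mz(pmz, z, k) for k in range(len(iso))])
        f_iso_mz = frag_mz + chem.ISOTOPE_SPACING  # fragment M+1, charge 1
        for off, cyc in enumerate(range(c0, c1)):
            h = g[off]
            if h < 1e-3:
                continue
            jit = 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, len(iso))
            ms1_mz[cyc].append(iso_mz * jit)
            ms1_int[cyc].append(iso * h)
            if widx is not None and len(frag_mz):
                jf = 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, len(frag_mz))
                ji = 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, len(frag_mz))
                ms2_mz[cyc][widx].append(
                    np.concatenate([frag_mz * jf, f_iso_mz * ji])
                )
                ms2_int[cyc][widx].append(
                    np.concatenate(
                        [frag_h * h, frag_h * h * cfg.fragment_isotope_ratio]
                    )
                )

    for i, e in enumerate(entries):
        if not present[i]:
            continue
        widx = window_of(e.precursor_mz)
        if widx is None:
            raise ValueError(
                f"precursor m/z {e.precursor_mz:.3f} outside every isolation window"
            )
        frag_mz = np.array([f.mz for f in e.fragments])
        frag_h = np.array([f.library_intensity for f in e.fragments])
        emit(e.precursor_mz, e.precursor_charge, frag_mz, frag_h,
             abund[i], apex_s[i], sigma[i], widx)

    # co-eluting interference: random peptides outside the library
    n_interf = round(cfg.interference_rate * n)
    made = 0
    while made < n_interf:
        seq = _random_peptide(rng, cfg, False)
        z = 2 if rng.random() < 0.7 else 3
        pmz = chem.precursor_mz(seq, z)
        widx = window_of(pmz)
        if widx is None:
            continue
        theo = [(ann, q, mz) for ann, q, mz in
                speclib.theoretical_fragment_mzs(seq, z) if q == 1]
        k = min(8, len(theo))
        sel = rng.choice(len(theo), size=k, replace=False)
        fmz = np.array([theo[j][2] for j in sel])
        fh = np.exp(rng.normal(0.0, 1.0, k))
        fh /= fh.max()
        a = cfg.abundance_median * np.exp(rng.normal(0.0, cfg.abundance_sigma))
        mu = float(rng.uniform(rt[0], rt[-1]))
        emit(pmz, z, fmz, fh, a, mu, cfg.peak_width_s, widx)
        made += 1

    # noise floor
    lo, hi = cfg.window_range
    for cyc in range(cfg.n_cycles_total):
        k = rng.poisson(cfg.noise_peaks_per_spectrum)
        if k:
            ms1_mz[cyc].append(rng.uniform(lo, hi, k))
            ms1_int[cyc].append(rng.exponential(cfg.noise_floor, k))
        for w in range(cfg.n_windows):
            k = rng.poisson(cfg.noise_peaks_per_spectrum)
            if k:
                ms2_mz[cyc][w].append(rng.uniform(100.0, 1800.0, k))
                ms2_int[cyc][w].append(rng.exponential(cfg.noise_floor, k))

    def build(mzs, ints) -> Spectrum:
        if not mzs:
            return Spectrum(np.empty(0), np.empty(0))
        return Spectrum(np.concatenate(mzs), np.concatenate(ints))

    ms1 = [build(ms1_mz[c], ms1_int[c]) for c in range(cfg.n_cycles_total)]
    ms2 = [
        [build(ms2_mz[c][w], ms2_int[c][w]) for w in range(cfg.n_windows)]
        for c in range(cfg.n_cycles_total)
    ]
    run = RunData(rt_per_cycle=rt, isolation_windows=windows, ms1=ms1, ms2=ms2)

    truth = pd.DataFrame({
        "modified_sequence": [e.modified_sequence for e in entries],
        "precursor_charge": [e.precursor_charge for e in entries],
        "present": present,
        "apex_s": apex_s,
        "apex_cycle": apex_cycle,
        "abundance": abund,
        "group": groups,
        "ratio": ratios,
    })
    return SynthExperiment(library=entries, run=run, truth=truth, config=cfg)


def generate_rsm_training_set(
    cfg: SynthConfig,
    n_rsms: int,
    seed: int = 0,
    params=None,
    decoy_method: str = "shuffle",
):
    """Balanced labeled RSM training set assembled via the real RSM module.

    Targets are assembled at their generator-assigned apex cycle; decoys at
    the cycle their (inherited) normalized RT maps to. Returns
    (rsms [n, rows, cycles] normalized, labels, groups) with n_rsms split
    evenly between classes.
    """
    from . import decoys as _decoys
    from . import rsm as _rsm

    params = params or _rsm.RSMParams()
    n_per_class = n_rsms // 2
    cfg = SynthConfig(**{**cfg.__dict__, "n_precursors": n_per_class,
                         "fraction_present": 1.0, "seed": seed})
    exp = generate_experiment(cfg)
    dec = _decoys.generate_decoys(exp.library, _decoys.DecoyMethod(decoy_method, seed))
    entries = exp.library + dec
    # a decoy shares its source target's normalized RT, hence its apex cycle
    # and its train/validation group
    slope, intercept = cfg.rt_map
    rt = exp.run.rt_per_cycle
    gid = {e.normalized_rt: i for i, e in enumerate(exp.library)}
    centers = [
        int(np.abs(rt - (slope * e.normalized_rt + intercept)).argmin())
        for e in entries
    ]
    traces = _rsm.extract_traces_for_entries(exp.run, entries, params)
    X = np.empty((len(entries), params.n_rows, params.n_cycles), dtype=np.float32)
    for i, tr in enumerate(traces):
        aw = _rsm.assemble_windows(tr, [centers[i]], params)
        X[i] = _rsm.normalize_matrices(aw.matrices)[0]
    y = np.array([0.0 if e.is_decoy else 1.0 for e in entries])
    groups = np.array([gid[e.normalized_rt] for e in entries])
    return X, y, groups


# ---------------------------------------------------------------------------
# raw-file writers (minimal, centroided; read back with pyteomics)


def _b64(arr: np.ndarray, big_endian: bool = False) -> str:
    dtype = ">f8" if big_endian else "<f8"
    return base64.b64encode(np.asarray(arr, dtype=dtype).tobytes()).decode()


def write_mzml(run: RunData, path) -> None:
    """Write the run as minimal centroided mzML 1.1."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UO" URI="http://ontologies.berkeleybop.org/uo.obo"/>'
        "</cvList>",
    ]
    n_spectra = run.n_cycles * (1 + len(run.isolation_windows))
    lines.append(f'<run id="synthetic"><spectrumList count="{n_spectra}">')
    idx = 0

    def spectrum_xml(spec: Spectrum, level: int, rt_s: float,
                     window: tuple[float, float] | None) -> str:
        nonlocal idx
        mz_b64 = _b64(spec.mz)
        int_b64 = _b64(spec.intensity)
        parts = [
            f'<spectrum index="{idx}" id="scan={idx + 1}" '
            f'defaultArrayLength="{spec.mz.size}">',
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{level}"/>',
            '<cvParam cvRef="MS" accession="MS:1000127" '
            'name="centroid spectrum" value=""/>',
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt_s:.6f}" unitCvRef="UO" unitAccession="UO:0000010" '
            'unitName="second"/></scan></scanList>',
        ]
        if window is not None:
            lo, hi = window
            center = 0.5 * (lo + hi)
            parts.append(
                '<precursorList count="1"><precursor><isolationWindow>'
                f'<cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{center:.6f}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{center - lo:.6f}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{hi - center:.6f}"/>'
                "</isolationWindow>"
                '<selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{center:.6f}"/>'
                "</selectedIon></selectedIonList>"
                "<activation/></precursor></precursorList>"
            )
        parts.append(
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
            f"<binary>{mz_b64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
            f"<binary>{int_b64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
        idx += 1
        return "".join(parts)

    for c in range(run.n_cycles):
        rt_s = float(run.rt_per_cycle[c])
        lines.append(spectrum_xml(run.ms1[c], 1, rt_s, None))
        for w, (lo, hi) in enumerate(run.isolation_windows):
            lines.append(spectrum_xml(run.ms2_spectrum(c, w), 2, rt_s, (lo, hi)))
    lines.append("</spectrumList></run></mzML>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_mzxml(run: RunData, path) -> None:
    """Write the run as minimal centroided mzXML 3.2 (flat scan list)."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
    ]
    n_spectra = run.n_cycles * (1 + len(run.isolation_windows))
    lines.append(f'<msRun scanCount="{n_spectra}">')
    num = 0

    def scan_xml(spec: Spectrum, level: int, rt_s: float,
                 window: tuple[float, float] | None) -> str:
        nonlocal num
        num += 1
        interleaved = np.empty(2 * spec.mz.size)
        interleaved[0::2] = spec.mz
        interleaved[1::2] = spec.intensity
        payload = _b64(interleaved, big_endian=True)
        parts = [
            f'<scan num="{num}" msLevel="{level}" peaksCount="{spec.mz.size}" '
            f'centroided="1" retentionTime="PT{rt_s:.6f}S">'
        ]
        if window is not None:
            lo, hi = window
            parts.append(
                f'<precursorMz precursorIntensity="0" '
                f'windowWideness="{hi - lo:.6f}">{0.5 * (lo + hi):.6f}</precursorMz>'
            )
        parts.append(
            '<peaks compressionType="none" compressedLen="0" precision="64" '
            f'byteOrder="network" contentType="m/z-int">{payload}</peaks></scan>'
        )
        return "".join(parts)

    for c in range(run.n_cycles):
        rt_s = float(run.rt_per_cycle[c])
        lines.append(scan_xml(run.ms1[c], 1, rt_s, None))
        for w, (lo, hi) in enumerate(run.isolation_windows):
            lines.append(scan_xml(run.ms2_spectrum(c, w), 2, rt_s, (lo, hi)))
    lines.append("</msRun></mzXML>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
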