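"""Transition-list spectral libraries.

A library is a flat tab-separated transition list (one row per fragment ion,
OpenSWATH column convention by default) grouped here into
:class:`LibraryEntry` records, one per (modified sequence, precursor charge).
Also hosts the theoretical b/y fragment enumeration used by the *self* part
of the representative spectral matrix, and the pseudo-modification m/z shift
used by the deamidation confidence benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from . import chem

__all__ = [
    "FragmentIon",
    "LibraryEntry",
    "PseudoModParams",
    "LibraryFormatError",
    "DEFAULT_DIALECT",
    "parse_library",
    "write_library",
    "entries_to_frame",
    "theoretical_fragment_mzs",
    "apply_pseudo_modification_shift",
]


@dataclass(frozen=True)
class FragmentIon:
    """One annotated fragment ion of a library precursor."""

    annotation: str          # e.g. "y7"
    mz: float                # Th
    charge: int
    library_intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be > 0, got {self.mz}")
        if self.charge < 1:
            raise ValueError(f"fragment charge must be >= 1, got {self.charge}")
        if self.library_intensity < 0:
            raise ValueError("library intensity must be >= 0")


@dataclass
class LibraryEntry:
    """One precursor with its annotated fragments and metadata."""

    modified_sequence: str
    precursor_mz: float
    precursor_charge: int
    normalized_rt: float
    fragments: list[FragmentIon]
    protein_id: str
    is_decoy: bool = False

    def __post_init__(self):
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if not self.fragments:
            raise ValueError(
                f"entry {self.modified_sequence}/{self.precursor_charge} has no fragments"
            )
        seen = set()
        for f in self.fragments:
            key = (f.annotation, f.charge)
            if key in seen:
                raise ValueError(
                    f"duplicate fragment {key} in {self.modified_sequence}"
                )
            seen.add(key)

    @property
    def key(self) -> tuple[str, int]:
        return (self.modified_sequence, self.precursor_charge)

    @property
    def peptide_length(self) -> int:
        return len(chem.strip_modifications(self.modified_sequence))


@dataclass(frozen=True)
class PseudoModParams:
    """Parameters of the deamidation pseudo-mass-shift construction."""

    n_mods: int
    ion_charge: int
    true_shift: float = 0.9840
    pseudo_shift: float = 1.0227

    def __post_init__(self):
        if self.n_mods < 0:
            raise ValueError("n_mods must be >= 0")
        if self.ion_charge < 1:
            raise ValueError("ion_charge must be >= 1")


class LibraryFormatError(ValueError):
    pass


#: OpenSWATH-style transition list columns -> internal field names
DEFAULT_DIALECT: dict[str, str] = {
    "PrecursorMz": "precursor_mz",
    "ProductMz": "product_mz",
    "LibraryIntensity": "library_intensity",
    "NormalizedRetentionTime": "normalized_rt",
    "PeptideSequence": "peptide_sequence",
    "FullUniModPeptideName": "modified_sequence",
    "PrecursorCharge": "precursor_charge",
    "ProductCharge": "product_charge",
    "FragmentType": "fragment_type",
    "FragmentSeriesNumber": "fragment_series_number",
    "ProteinName": "protein_id",
    "decoy": "decoy",
}

_REQUIRED = [
    "precursor_mz", "product_mz", "library_intensity", "normalized_rt",
    "modified_sequence", "precursor_charge", "product_charge",
    "fragment_type", "fragment_series_number", "protein_id",
]


def parse_library(path, dialect: dict[str, str] | None = None) -> list[LibraryEntry]:
    """Read a tab-separated transition list into grouped library entries.

    All fragment rows of a precursor are kept verbatim; any top-N selection
    happens later, at RSM assembly or two-species library construction.
    """
    dialect = dialect or DEFAULT_DIALECT
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise LibraryFormatError(f"library file {path} contains no transitions")
    df = df.rename(columns=dialect)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        # report the external header names for the missing internal fields
        inv = {v: k for k, v in dialect.items()}
        names = ", ".join(inv.get(c, c) for c in missing)
        raise LibraryFormatError(f"library file {path} lacks required column(s): {names}")
    if "decoy" not in df.columns:
        df["decoy"] = 0

    entries = []
    for (seq, z), grp in df.groupby(
        ["modified_sequence", "precursor_charge"], sort=False
    ):
        fragments = [
            FragmentIon(
                annotation=f"{r.fragment_type}{int(r.fragment_series_number)}",
                mz=float(r.product_mz),
                charge=int(r.product_charge),
                library_intensity=float(r.library_intensity),
            )
            for r in grp.itertuples()
        ]
        entries.append(
            LibraryEntry(
                modified_sequence=str(seq),
                precursor_mz=float(grp["precursor_mz"].iloc[0]),
                precursor_charge=int(z),
                normalized_rt=float(grp["normalized_rt"].iloc[0]),
                fragments=fragments,
                protein_id=str(grp["protein_id"].iloc[0]),
                is_decoy=bool(int(grp["decoy"].iloc[0])),
            )
        )
    return entries


def entries_to_frame(entries: list[LibraryEntry]) -> pd.DataFrame:
    """Flatten entries back to the transition-list table (default dialect)."""
    rows = []
    for e in entries:
        plain = chem.strip_modifications(e.modified_sequence)
        for f in e.fragments:
            rows.append({
                "PrecursorMz": e.precursor_mz,
                "ProductMz": f.mz,
                "LibraryIntensity": f.library_intensity,
                "NormalizedRetentionTime": e.normalized_rt,
                "PeptideSequence": plain,
                "FullUniModPeptideName": e.modified_sequence,
                "PrecursorCharge": e.precursor_charge,
                "ProductCharge": f.charge,
                "FragmentType": f.annotation[0],
                "FragmentSeriesNumber": int(f.annotation[1:]),
                "ProteinName": e.protein_id,
                "decoy": int(e.is_decoy),
            })
    return pd.DataFrame(rows)


def write_library(entries: list[LibraryEntry], path) -> None:
    entries_to_frame(entries).to_csv(path, sep="\t", index=False)


def fragment_charges_for_precursor(precursor_charge: int) -> tuple[int, ...]:
    """Fragment charge states considered for the theoretical (*self*) ions."""
    return (1,) if precursor_charge <= 2 else (1, 2)


def theoretical_fragment_mzs(
    modified_sequence: str, precursor_charge: int
) -> list[tuple[str, int, float]]:
    """Enumerate theoretical b/y fragment ions for a precursor.

    Charge-2 precursors (and below) yield singly charged fragments only;
    charge >= 3 yields both 1+ and 2+, following the convention used for the
    *self* XIC block. Deterministic order: (series, index, charge).
    """
    masses = chem.residue_masses(modified_sequence)
    L = len(masses)
    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)
    out: list[tuple[str, int, float]] = []
    charges = fragment_charges_for_precursor(precursor_charge)
    for series in ("b", "y"):
        for idx in range(1, L):
            if series == "b":
                neutral = prefix[idx]
            else:
                neutral = prefix[L] - prefix[L - idx] + chem.WATER_MASS
            for q in charges:
                out.append((f"{series}{idx}", q, neutral / q + chem.PROTON_MASS))
    return out


def apply_pseudo_modification_shift(mz: float, params: PseudoModParams) -> float:
    """Shift a deamidation-bearing ion's m/z to its pseudo-modification value.

    Adds N x (pseudo - true)/C, turning a correct-mass library into one whose
    deamidated ions are off by ~0.0387 Th per modification and unit charge.
    """
    return mz + params.n_mods * (params.pseudo_shift - params.true_shift) / params.ion_charge


def count_deamidations_in_fragment(
    entry: LibraryEntry, annotation: str
) -> int:
    """Number of deamidated residues covered by a b/y fragment of the entry."""
    tokens = chem.parse_modified_sequence(entry.modified_sequence)
    series, idx = annotation[0], int(annotation[1:])
    if series == "b":
        covered = tokens[:idx]
    elif series == "y":
        covered = tokens[len(tokens) - idx:]
    else:
        raise ValueError(f"unsupported ion series in annotation {annotation!r}")
    return sum(1 for _, u in covered if u == chem.DEAMIDATION_UNIMOD)


def make_pseudo_shift_library(entries: list[LibraryEntry]) -> list[LibraryEntry]:
    """Apply the pseudo-modification shift to every deamidation-bearing ion.

    Precursor and fragment m/z of entries carrying deamidation are moved by
    N x (1.0227 - 0.9840)/C; unmodified entries are returned unchanged.
    """
    out = []
    for e in entries:
        tokens = chem.parse_modified_sequence(e.modified_sequence)
        n_total = sum(1 for _, u in tokens if u == chem.DEAMIDATION_UNIMOD)
        if n_total == 0:
            out.append(e)
            continue
        new_frags = []
        for f in e.fragments:
            n = count_deamidations_in_fragment(e, f.annotation)
            new_frags.append(
                replace(
                    f,
                    mz=apply_pseudo_modification_shift(
                        f.mz, PseudoModParams(n_mods=n, ion_charge=f.charge)
                    ),
                )
            )
        out.append(
            replace(
                e,
                precursor_mz=apply_pseudo_modification_shift(
                    e.precursor_mz,
                    PseudoModParams(n_mods=n_total, ion_charge=e.precursor_charge),
                ),
                fragments=new_frags,
            )
        )
    return out
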