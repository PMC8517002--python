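"""Monoisotopic mass bookkeeping for peptides and their fragment ions.

Residue masses come from pyteomics; modifications are encoded as UniMod-style
bracketed tags inside the sequence string, e.g. ``PEPTC(UniMod:4)IDER``.
Only the closed set of modifications needed here is supported.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

PROTON_MASS = 1.007276  # Da, fixed constant used for all charge adjustments
WATER_MASS = _pmass.calculate_mass(formula="H2O")
ISOTOPE_SPACING = 1.0033548  # Da, C13-C12 difference used for (M+k)/q traces

#: monoisotopic mass deltas of the supported UniMod modifications
UNIMOD_DELTAS: dict[int, float] = {
    1: 42.010565,   # acetyl
    4: 57.021464,   # carbamidomethyl
    7: 0.984016,    # deamidation (NH -> O on Asn/Gln)
    35: 15.994915,  # oxidation
}

DEAMIDATION_UNIMOD = 7
DEAMIDATION_SHIFT = UNIMOD_DELTAS[DEAMIDATION_UNIMOD]  # 0.9840 Da

_TOKEN_RE = re.compile(r"([A-Z])(\(UniMod:(\d+)\))?")


class UnknownResidueError(ValueError):
    """Sequence contains a residue or modification tag outside the alphabet."""


def parse_modified_sequence(seq: str) -> list[tuple[str, int | None]]:
    """Split a modified sequence into (residue, unimod_id-or-None) tokens.

    Raises :class:`UnknownResidueError` on any unparseable token.
    """
    tokens: list[tuple[str, int | None]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(seq):
        if m.start() != pos:
            raise UnknownResidueError(
                f"unparseable token {seq[pos:m.start()]!r} in sequence {seq!r}"
            )
        pos = m.end()
        aa = m.group(1)
        if aa not in _pmass.std_aa_mass:
            raise UnknownResidueError(f"unknown residue {aa!r} in sequence {seq!r}")
        unimod = None
        if m.group(3) is not None:
            unimod = int(m.group(3))
            if unimod not in UNIMOD_DELTAS:
                raise UnknownResidueError(
                    f"unsupported modification UniMod:{unimod} in sequence {seq!r}"
                )
        tokens.append((aa, unimod))
    if pos != len(seq) or not tokens:
        raise UnknownResidueError(f"unparseable sequence {seq!r}")
    return tokens


def strip_modifications(seq: str) -> str:
    """Plain amino-acid sequence with modification tags removed."""
    return "".join(aa for aa, _ in parse_modified_sequence(seq))


def residue_masses(seq: str) -> list[float]:
    """Monoisotopic residue masses (modification deltas included), N- to C-term."""
    return [
        _pmass.std_aa_mass[aa] + (UNIMOD_DELTAS[u] if u is not None else 0.0)
        for aa, u in parse_modified_sequence(seq)
    ]


def peptide_neutral_mass(seq: str) -> float:
    """Monoisotopic neutral mass of the (modified) peptide."""
    return sum(residue_masses(seq)) + WATER_MASS


def precursor_mz(seq: str, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return peptide_neutral_mass(seq) / charge + PROTON_MASS


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Invert m/z back to neutral mass M given the charge."""
    return charge * (mz - PROTON_MASS)


def isotope_mz(mz: float, charge: int, k: int) -> float:
    """m/z of the (M + k)/q isotopologue trace (k may be negative)."""
    return mz + k * ISOTOPE_SPACING / charge
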