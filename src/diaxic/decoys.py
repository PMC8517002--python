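"""Decoy library generation.

One decoy per target, by one of five sequence-level transforms: shuffle
(default), reverse, pseudo-reverse, mutate, shift. Sequence-transforming
methods recompute fragment m/z from the decoy sequence while keeping each
fragment's annotation, charge and library intensity; *shift* keeps the
sequence and displaces every fragment m/z by a fixed offset per charge.

Randomness is order-independent: each entry draws from a stream seeded by
hashing (library seed, target sequence), so shuffling the library does not
change any individual decoy.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import chem, speclib
from .speclib import FragmentIon, LibraryEntry

logger = logging.getLogger(__name__)

METHODS = ("shuffle", "reverse", "pseudo-reverse", "mutate", "shift")

#: residue substitution pairs used by *mutate* (mirrors the usual
#: mass-changing swap heuristic); symmetric closure applied below
_MUTATE_PAIRS = [
    ("G", "A"), ("S", "T"), ("C", "M"), ("L", "I"), ("D", "E"),
    ("N", "Q"), ("K", "R"), ("F", "Y"), ("V", "P"), ("H", "W"),
]
_MUTATE_TABLE = {a: b for a, b in _MUTATE_PAIRS}
_MUTATE_TABLE.update({b: a for a, b in _MUTATE_PAIRS})

DEFAULT_SHIFT_DA = 10.0  # Da per charge, for the *shift* method
_RETRY_LIMIT = 10


@dataclass(frozen=True)
class DecoyMethod:
    name: str = "shuffle"
    seed: int = 0
    shift_da: float = DEFAULT_SHIFT_DA

    def __post_init__(self):
        if self.name not in METHODS:
            raise ValueError(f"unknown decoy method {self.name!r}; choose from {METHODS}")


class DecoyGenerationError(RuntimeError):
    pass


def _entry_rng(seed: int, sequence: str) -> np.random.Generator:
    h = hashlib.sha256(f"{seed}:{sequence}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def _transform_tokens(tokens, method: DecoyMethod, rng) -> list:
    """Apply the sequence-level transform; C-terminal residue stays anchored
    for shuffle/pseudo-reverse/mutate (tryptic anchor)."""
    if method.name == "reverse":
        return tokens[::-1]
    if method.name == "pseudo-reverse":
        return tokens[:-1][::-1] + [tokens[-1]]
    if method.name == "shuffle":
        head = list(tokens[:-1])
        # Fisher-Yates over all but the C-terminal residue
        for i in range(len(head) - 1, 0, -1):
            j = int(rng.integers(0, i + 1))
            head[i], head[j] = head[j], head[i]
        return head + [tokens[-1]]
    if method.name == "mutate":
        out = list(tokens)
        L = len(out)
        for pos in sorted({1, L // 2, L - 2}):
            if 0 <= pos < L - 1:
                aa, u = out[pos]
                out[pos] = (_MUTATE_TABLE.get(aa, aa), u)
        return out
    return list(tokens)  # shift: sequence unchanged


def _tokens_to_sequence(tokens) -> str:
    return "".join(
        aa if u is None else f"{aa}(UniMod:{u})" for aa, u in tokens
    )


def generate_decoy(
    entry: LibraryEntry,
    method: DecoyMethod,
    target_sequences: frozenset[str] | None = None,
) -> LibraryEntry | None:
    """Build the decoy for one target entry.

    Returns None (with a warning) if a distinct decoy sequence cannot be
    produced within the retry limit (e.g. a homopolymer under shuffle).
    ``target_sequences`` is the set of all target modified sequences the
    decoy must avoid colliding with.
    """
    if entry.is_decoy:
        raise ValueError("cannot generate a decoy from a decoy entry")
    rng = _entry_rng(method.seed, entry.modified_sequence)
    tokens = chem.parse_modified_sequence(entry.modified_sequence)
    avoid = target_sequences if target_sequences is not None else frozenset(
        [entry.modified_sequence]
    )

    if method.name == "shift":
        frags = [
            replace(f, mz=f.mz + method.shift_da / f.charge)
            for f in entry.fragments
        ]
        return replace(
            entry,
            fragments=frags,
            is_decoy=True,
            protein_id=f"DECOY_{entry.protein_id}",
        )

    decoy_seq = None
    for _ in range(_RETRY_LIMIT):
        cand_tokens = _transform_tokens(tokens, method, rng)
        cand = _tokens_to_sequence(cand_tokens)
        if cand not in avoid:
            decoy_seq = cand
            break
        if method.name in ("reverse", "pseudo-reverse", "mutate"):
            break  # deterministic transforms cannot improve on retry
    if decoy_seq is None:
        warnings.warn(
            f"could not derive a distinct decoy for {entry.modified_sequence} "
            f"({method.name}); entry skipped"
        )
        logger.warning("decoy generation skipped for %s", entry.modified_sequence)
        return None

    theo = dict(
        ((ann, q), mz)
        for ann, q, mz in speclib.theoretical_fragment_mzs(
            decoy_seq, entry.precursor_charge
        )
    )
    frags = []
    for f in entry.fragments:
        mz = theo.get((f.annotation, f.charge))
        if mz is None:
            # annotation outside the decoy's b/y range (should not happen for
            # well-formed libraries); keep the target m/z shifted by nothing
            mz = f.mz
        frags.append(FragmentIon(f.annotation, mz, f.charge, f.library_intensity))
    return LibraryEntry(
        modified_sequence=decoy_seq,
        precursor_mz=chem.precursor_mz(decoy_seq, entry.precursor_charge),
        precursor_charge=entry.precursor_charge,
        normalized_rt=entry.normalized_rt,
        fragments=frags,
        protein_id=f"DECOY_{entry.protein_id}",
        is_decoy=True,
    )


def generate_decoys(
    entries: list[LibraryEntry], method: DecoyMethod
) -> list[LibraryEntry]:
    """One decoy per target; targets pass through untouched."""
    targets = [e for e in entries if not e.is_decoy]
    avoid = frozenset(e.modified_sequence for e in targets)
    decoys = []
    for e in targets:
        d = generate_decoy(e, method, avoid)
        if d is not None:
            decoys.append(d)
    return decoys
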