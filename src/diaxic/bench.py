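"""Benchmarking utilities.

Two orthogonal validations of the decoy-based error estimates:

* the two-species library test — spike an equal number of foreign-species
  precursors into the library; foreign identifications above a score cutoff
  give a proxy FDR = foreign / all that is independent of the decoys; and
* the deamidation confidence test — analyze the same run with the correct
  deamidation mass shift (0.9840 Da) and with a close pseudo shift
  (1.0227 Da, applied as N x (1.0227 - 0.9840)/C per ion); a trustworthy
  scorer finds many identifications in the first analysis and few in the
  second.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import deep_rep, pipeline as _pipeline, speclib
from .raw_io import RunData
from .speclib import LibraryEntry

__all__ = [
    "TwoSpeciesResult", "build_two_species_library", "proxy_fdr_curve",
    "proxy_fdr_at_cutoff", "deamidation_confidence_test",
]

SPECIES_SAMPLE = "sample"
SPECIES_FOREIGN = "foreign"


@dataclass
class TwoSpeciesResult:
    """Proxy-FDR curve of a two-species analysis."""

    curve: pd.DataFrame        # cutoff, proxy_fdr, n_true_species
    species: dict              # (sequence, charge) -> species label


def _truncate_fragments(entry: LibraryEntry, k: int = 6) -> LibraryEntry:
    order = sorted(
        range(len(entry.fragments)),
        key=lambda i: (-entry.fragments[i].library_intensity, i),
    )
    frags = [entry.fragments[i] for i in sorted(order[:k])]
    return replace(entry, fragments=frags)


def build_two_species_library(
    sample_lib: list[LibraryEntry],
    foreign_lib: list[LibraryEntry],
    seed: int = 0,
) -> tuple[list[LibraryEntry], dict]:
    """Merge equal numbers of sample and foreign precursors.

    Foreign entries whose sequence occurs in the sample library are
    discarded; a seeded uniform subset of exactly |sample| foreign entries
    is spiked in; every precursor keeps only its six most intense fragments.
    Returns (merged library, species labels by (sequence, charge)).
    """
    sample_seqs = {e.modified_sequence for e in sample_lib}
    eligible = [e for e in foreign_lib if e.modified_sequence not in sample_seqs]
    n = len(sample_lib)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} foreign precursors remain after overlap "
            f"filtering; {n} required to match the sample library"
        )
    rng = np.random.default_rng(seed)
    picked = [eligible[i] for i in sorted(
        rng.choice(len(eligible), size=n, replace=False)
    )]
    merged = [_truncate_fragments(e) for e in sample_lib] + \
             [_truncate_fragments(e) for e in picked]
    species = {e.key: SPECIES_SAMPLE for e in sample_lib}
    species.update({e.key: SPECIES_FOREIGN for e in picked})
    return merged, species


def proxy_fdr_curve(results, species_labels: dict) -> TwoSpeciesResult:
    """Proxy FDR at each foreign precursor's score taken as the cutoff.

    ``results`` are per-precursor scored results (decoys are ignored); every
    target must carry a species label. Proxy FDR = #foreign above cutoff /
    #all above cutoff, paired with the count of true-species identifications.
    """
    targets = [r for r in results if not r.is_decoy]
    labels = []
    for r in targets:
        key = (r.entry.modified_sequence, r.entry.precursor_charge)
        if key not in species_labels:
            raise ValueError(f"missing species label for {key}")
        labels.append(species_labels[key])
    labels = np.array(labels)
    if not (labels == SPECIES_FOREIGN).any():
        raise ValueError("no foreign-species precursors among the results")
    scores = np.array([r.discriminant_score for r in targets])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    foreign_cum = np.cumsum(labels == SPECIES_FOREIGN)
    true_cum = np.cumsum(labels == SPECIES_SAMPLE)
    rows = []
    for i in np.flatnonzero(labels == SPECIES_FOREIGN):
        # include score ties above this foreign precursor
        j = np.searchsorted(-scores, -scores[i], side="right") - 1
        rows.append({
            "cutoff": scores[i],
            "proxy_fdr": foreign_cum[j] / (foreign_cum[j] + true_cum[j]),
            "n_true_species": int(true_cum[j]),
        })
    curve = pd.DataFrame(rows).sort_values(
        "cutoff", ascending=False
    ).reset_index(drop=True)
    return TwoSpeciesResult(curve=curve, species=dict(species_labels))


def proxy_fdr_at_cutoff(results, species_labels: dict, cutoff: float) -> float:
    """Proxy FDR among targets scoring at or above an externally chosen cutoff."""
    targets = [r for r in results if not r.is_decoy
               and r.discriminant_score >= cutoff]
    if not targets:
        return 0.0
    n_foreign = sum(
        1 for r in targets
        if species_labels[(r.entry.modified_sequence,
                           r.entry.precursor_charge)] == SPECIES_FOREIGN
    )
    return n_foreign / len(targets)


def deamidation_confidence_test(
    run: RunData,
    deamid_lib: list[LibraryEntry],
    model: deep_rep.RepresentationModel,
    config: _pipeline.PipelineConfig | None = None,
    q_threshold: float = 0.01,
) -> tuple[int, int]:
    """Count deamidated identifications under the true and pseudo mass shifts.

    The run is analyzed twice with identical settings and seeds: once with
    the library as given (true 0.9840 Da deamidation masses) and once with
    every deamidation-bearing ion shifted by N x (1.0227 - 0.9840)/C.
    Returns (n_true_shift, n_pseudo_shift) deamidated identifications at
    the matched q-value threshold.
    """
    from . import chem

    def is_deamidated(e: LibraryEntry) -> bool:
        return any(
            u == chem.DEAMIDATION_UNIMOD
            for _, u in chem.parse_modified_sequence(e.modified_sequence)
        )

    if not any(is_deamidated(e) for e in deamid_lib):
        raise ValueError("library contains no deamidated precursors")
    config = config or _pipeline.PipelineConfig()
    pseudo_lib = speclib.make_pseudo_shift_library(deamid_lib)

    counts = []
    for lib in (deamid_lib, pseudo_lib):
        res = _pipeline.run_pipeline(run, lib, model, config)
        t = res.table
        hits = t[(~t["is_decoy"]) & (t["q_value"] <= q_threshold)]
        counts.append(int(sum(
            1 for s in hits["modified_sequence"]
            if "(UniMod:7)" in s
        )))
    return counts[0], counts[1]
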