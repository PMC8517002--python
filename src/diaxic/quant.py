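"""Correlation-weighted peptide and protein quantification.

A precursor's quantity is the double sum over its top library fragments

    Q = sum_i sum_j Corr(C_i, C_j) * Area(C_i)

taken over the (up to) six library XICs ranked by the sum of their Pearson
correlations with the other library XICs — i.e. the first rows of the
sorted library@r block of the best candidate's RSM. The double sum runs over
all (i, j) pairs including i = j, so each fragment's weight is 1 plus the
sum of its cross-correlations; anti-correlated interference can contribute
negative weight and is deliberately not clipped. Areas are trapezoidal
integrals over the RSM window with the run's per-cycle RT spacing, in
seconds. Protein quantities are the sum of the top-three precursor
quantities per protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rsm import RSM, pearson

__all__ = [
    "QuantParams", "QuantRecord", "weighted_area_quantity",
    "quantify_precursor", "quantify_with_self_fragments", "quantify_protein",
]

TOP_FRAGMENTS = 6
TOP_PRECURSORS_PER_PROTEIN = 3


@dataclass(frozen=True)
class QuantParams:
    top_fragments: int = TOP_FRAGMENTS
    top_precursors: int = TOP_PRECURSORS_PER_PROTEIN


@dataclass
class QuantRecord:
    precursor_key: tuple[str, int]
    protein_id: str
    quantity: float
    fragments_used: int


def _areas(xics: np.ndarray, rt_spacing_s) -> np.ndarray:
    """Trapezoidal area of each XIC row over the window, seconds units."""
    if np.isscalar(rt_spacing_s):
        x = np.arange(xics.shape[1]) * float(rt_spacing_s)
    else:
        x = np.asarray(rt_spacing_s, dtype=np.float64)
    return np.trapezoid(xics, x=x, axis=1)


def weighted_area_quantity(xics: np.ndarray, rt_spacing_s) -> tuple[float, int]:
    """Evaluate the correlation-weighted double sum on a set of XIC rows.

    Zero rows (zero-filled padding) are dropped first. Returns (Q, n_used).
    """
    xics = np.asarray(xics, dtype=np.float64)
    nonzero = np.flatnonzero(xics.any(axis=1))
    if nonzero.size == 0:
        warnings.warn("all fragment XICs are zero; quantity set to 0")
        return 0.0, 0
    rows = xics[nonzero]
    n = rows.shape[0]
    areas = _areas(rows, rt_spacing_s)
    q = 0.0
    for i in range(n):
        w = sum(pearson(rows[i], rows[j]) for j in range(n))  # includes i == j
        q += w * areas[i]
    return float(q), int(n)


def quantify_precursor(
    rsm: RSM,
    rt_spacing_s: float,
    params: QuantParams | None = None,
    lib_block: np.ndarray | None = None,
) -> QuantRecord:
    """Quantity of one precursor from the top library rows of its best RSM.

    ``lib_block`` may supply the unnormalized sorted library@r rows when the
    RSM matrix itself has been normalized for the model.
    """
    params = params or QuantParams()
    block = lib_block if lib_block is not None else rsm.part("library_r")
    top = block[: params.top_fragments]
    q, n_used = weighted_area_quantity(top, rt_spacing_s)
    e = rsm.precursor_ref
    return QuantRecord(
        precursor_key=(e.modified_sequence, e.precursor_charge),
        protein_id=e.protein_id,
        quantity=q,
        fragments_used=n_used,
    )


def quantify_with_self_fragments(
    rsm: RSM,
    k: int,
    rt_spacing_s: float,
    params: QuantParams | None = None,
    lib_block: np.ndarray | None = None,
) -> QuantRecord:
    """Optional mode: add the top-k self fragments' weighted areas.

    Each of the k highest-ranked self rows (already sorted by correlation
    with the first library row) contributes Corr(self_i, library_1) times
    its area on top of the base quantity.
    """
    if not 3 <= k <= 15:
        raise ValueError(f"k must be in 3..15, got {k}")
    base = quantify_precursor(rsm, rt_spacing_s, params, lib_block)
    self_rows = rsm.part("self")[:k]
    block = lib_block if lib_block is not None else rsm.part("library_r")
    first_lib = block[0]
    extra = 0.0
    used = 0
    for row in self_rows:
        if not row.any():
            continue
        extra += pearson(row, first_lib) * _areas(row[None], rt_spacing_s)[0]
        used += 1
    return QuantRecord(
        precursor_key=base.precursor_key,
        protein_id=base.protein_id,
        quantity=base.quantity + float(extra),
        fragments_used=base.fragments_used + used,
    )


def quantify_protein(
    records: list[QuantRecord], params: QuantParams | None = None
) -> float:
    """Sum of the top-three precursor quantities (all, if fewer)."""
    params = params or QuantParams()
    if not records:
        raise ValueError("no precursor records for this protein")
    qs = sorted((r.quantity for r in records), reverse=True)
    return float(sum(qs[: params.top_precursors]))
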