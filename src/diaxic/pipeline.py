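"""End-to-end analysis of one DIA run against a spectral library.

Stage order: decoy check/generation -> RT anchor selection -> RT model fit
-> candidate enumeration (test-time augmentation) -> PU classifier training
-> scoring and per-precursor selection -> target-decoy FDR -> quantification
of passing targets -> protein rollup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decoys as _decoys
from . import deep_rep, discriminant, quant as _quant, rsm as _rsm, rt_norm
from .raw_io import RunData
from .speclib import LibraryEntry

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    rsm_params: _rsm.RSMParams = field(default_factory=_rsm.RSMParams)
    decoy_method: str = "shuffle"
    rt_model_kind: str = "linear"          # "linear" | "lowess"
    rt_anchors: int = rt_norm.DEFAULT_N_SAMPLE
    rt_half_window: int = discriminant.DEFAULT_RT_HALF_WINDOW
    dds_threshold: float = discriminant.DEFAULT_DDS_THRESHOLD
    classifier: str = "xgboost"            # "xgboost" | "random_forest"
    pu_folds: int = 2                      # 1 = single train/score pass
    fdr_level: float = 0.01
    quant_top_self: int | None = None      # optional 3..15 self-fragment mode
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")


@dataclass
class PipelineResult:
    results: list[discriminant.ScoredResult]
    table: pd.DataFrame
    protein_table: pd.DataFrame
    rt_model: rt_norm.RTModel
    anchors: list[rt_norm.RTAnchor]
    config: PipelineConfig

    def passing(self, q: float | None = None) -> pd.DataFrame:
        q = q if q is not None else self.config.fdr_level
        t = self.table
        return t[(~t["is_decoy"]) & (t["q_value"] <= q)]


def _quantify_passing(
    run: RunData,
    results: list[discriminant.ScoredResult],
    config: PipelineConfig,
) -> dict[tuple[str, int], _quant.QuantRecord]:
    """Re-assemble the best RSM window of each passing target and evaluate
    the correlation-weighted quantity there."""
    passing = [
        r for r in results
        if not r.is_decoy and r.q_value is not None
        and r.q_value <= config.fdr_level
    ]
    spacing = run.cycle_spacing_s
    records: dict[tuple[str, int], _quant.QuantRecord] = {}
    params = config.rsm_params
    chunk = 256
    for start in range(0, len(passing), chunk):
        part = passing[start:start + chunk]
        traces = _rsm.extract_traces_for_entries(
            run, [r.entry for r in part], params
        )
        for r, tr in zip(part, traces):
            aw = _rsm.assemble_windows(tr, [r.candidate.center_cycle], params)
            rsm_obj = _rsm.RSM(
                matrix=aw.matrices[0],
                part_layout=params.part_layout,
                center_cycle=r.candidate.center_cycle,
                precursor_ref=r.entry,
                params=params,
            )
            if config.quant_top_self is None:
                rec = _quant.quantify_precursor(
                    rsm_obj, spacing, lib_block=aw.lib_block[0]
                )
            else:
                rec = _quant.quantify_with_self_fragments(
                    rsm_obj, config.quant_top_self, spacing,
                    lib_block=aw.lib_block[0],
                )
            records[rec.precursor_key] = rec
    return records


def run_pipeline(
    run: RunData,
    library: list[LibraryEntry],
    model: deep_rep.RepresentationModel,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    targets = [e for e in library if not e.is_decoy]
    decoys = [e for e in library if e.is_decoy]
    if not decoys:
        logger.info("library has no decoys; generating with %s", config.decoy_method)
        decoys = _decoys.generate_decoys(
            targets, _decoys.DecoyMethod(config.decoy_method, config.seed)
        )
    entries = targets + decoys

    anchors = rt_norm.select_anchors(
        run, targets, model,
        n_sample=min(config.rt_anchors, len(targets)),
        seed=config.seed, params=config.rsm_params,
    )
    rt_model = rt_norm.fit_rt_model(
        anchors, kind=config.rt_model_kind, seed=config.seed
    )
    logger.info("RT model: %s, %d/%d anchor inliers",
                config.rt_model_kind, int(rt_model.inlier_mask.sum()), len(anchors))

    candidates = discriminant.build_candidates(
        run, entries, rt_model, model,
        params=config.rsm_params,
        rt_half_window=config.rt_half_window,
        dds_threshold=config.dds_threshold,
    )
    discriminant.cross_score_candidates(
        candidates, model_type=config.classifier,
        seed=config.seed, n_folds=config.pu_folds,
    )
    results = discriminant.score_and_select(candidates)
    discriminant.estimate_fdr(results, level="precursor")

    quants = _quantify_passing(run, results, config)
    prot_records: dict[str, list[_quant.QuantRecord]] = {}
    for rec in quants.values():
        prot_records.setdefault(rec.protein_id, []).append(rec)
    prot_quant = {
        pid: _quant.quantify_protein(recs) for pid, recs in prot_records.items()
    }

    rows = []
    for r in results:
        e = r.entry
        key = (e.modified_sequence, e.precursor_charge)
        rec = quants.get(key)
        rows.append({
            "modified_sequence": e.modified_sequence,
            "precursor_charge": e.precursor_charge,
            "precursor_mz": e.precursor_mz,
            "protein_id": e.protein_id,
            "is_decoy": e.is_decoy,
            "best_cycle": r.candidate.center_cycle,
            "apex_rt_s": float(run.rt_per_cycle[r.candidate.center_cycle]),
            "dds": r.candidate.dds,
            "discriminant_score": r.discriminant_score,
            "q_value": r.q_value,
            "quantity": rec.quantity if rec is not None else np.nan,
            "fragments_used": rec.fragments_used if rec is not None else 0,
        })
    table = pd.DataFrame(rows).sort_values(
        "discriminant_score", ascending=False
    ).reset_index(drop=True)
    protein_table = pd.DataFrame(
        [{"protein_id": pid, "quantity": q} for pid, q in prot_quant.items()]
    ).sort_values("protein_id").reset_index(drop=True) if prot_quant else \
        pd.DataFrame(columns=["protein_id", "quantity"])

    return PipelineResult(
        results=results, table=table, protein_table=protein_table,
        rt_model=rt_model, anchors=anchors, config=config,
    )
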