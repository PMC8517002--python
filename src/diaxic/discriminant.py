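"""Positive-unlabeled rescoring and decoy-based FDR control.

Candidate peak groups are enumerated around each precursor's predicted RT
(test-time augmentation: every cycle within a half-window whose dds clears a
threshold; the max-dds cycle as fallback so every precursor stays
scoreable). A run-specific nonlinear classifier — XGBoost (depth 6) or
random forest (depth 12, 200 trees) — is trained on all candidates with
decoys as confirmed negatives and targets as the unlabeled positive class.
The best-scoring candidate per precursor is kept, and q-values come from
the standard target-decoy estimator #decoys / #targets above a cutoff,
monotonized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import deep_rep, rsm as _rsm, rt_norm
from .raw_io import RunData
from .speclib import LibraryEntry

logger = logging.getLogger(__name__)

__all__ = [
    "CandidatePeakGroup", "ScoredResult", "enumerate_candidates",
    "build_candidates", "train_pu_classifier", "score_candidates",
    "score_and_select", "estimate_fdr",
]

DEFAULT_RT_HALF_WINDOW = 25   # cycles
DEFAULT_DDS_THRESHOLD = 0.5


@dataclass
class CandidatePeakGroup:
    """One RT-localized candidate RSM of one precursor."""

    entry: LibraryEntry
    center_cycle: int
    dds: float
    deep_features: np.ndarray        # 16
    aux_features: np.ndarray         # 6, see aux_feature_names()
    discriminant_score: float | None = None

    @property
    def is_decoy(self) -> bool:
        return self.entry.is_decoy

    @property
    def rt_deviation(self) -> float:
        return float(self.aux_features[3])

    def feature_vector(self) -> np.ndarray:
        return np.concatenate(([self.dds], self.deep_features, self.aux_features))


def aux_feature_names() -> list[str]:
    return [
        "precursor_mz", "precursor_charge", "peptide_length",
        "rt_deviation_cycles", "log_library_intensity", "n_nonzero_library_rows",
    ]


@dataclass
class ScoredResult:
    """Per-precursor best candidate after discriminant scoring."""

    entry: LibraryEntry
    candidate: CandidatePeakGroup
    discriminant_score: float
    q_value: float | None = None

    @property
    def is_decoy(self) -> bool:
        return self.entry.is_decoy


def _aux_features(aw: _rsm.AssembledWindows, predicted_cycle: int) -> np.ndarray:
    """[n_win, 6] auxiliary features for every window of one precursor."""
    e = aw.entry
    n_win = len(aw.centers)
    return np.column_stack([
        np.full(n_win, e.precursor_mz),
        np.full(n_win, float(e.precursor_charge)),
        np.full(n_win, float(e.peptide_length)),
        np.abs(aw.centers - predicted_cycle).astype(np.float64),
        np.log1p(aw.lib_sum),
        aw.lib_nonzero_rows.astype(np.float64),
    ])


def _candidates_from_windows(
    aw, dds, feats, predicted_cycle, dds_threshold
) -> list[CandidatePeakGroup]:
    aux = _aux_features(aw, predicted_cycle)
    keep = np.flatnonzero(dds >= dds_threshold)
    if keep.size == 0:
        keep = np.array([int(np.argmax(dds))])  # fallback: stay scoreable
    return [
        CandidatePeakGroup(
            entry=aw.entry,
            center_cycle=int(aw.centers[k]),
            dds=float(dds[k]),
            deep_features=feats[k],
            aux_features=aux[k],
        )
        for k in keep
    ]


def enumerate_candidates(
    run: RunData,
    entry: LibraryEntry,
    rt_model: rt_norm.RTModel,
    model: deep_rep.RepresentationModel,
    params: _rsm.RSMParams | None = None,
    rt_half_window: int = DEFAULT_RT_HALF_WINDOW,
    dds_threshold: float = DEFAULT_DDS_THRESHOLD,
) -> list[CandidatePeakGroup]:
    """Candidate peak groups of one precursor around its predicted RT."""
    params = params or _rsm.RSMParams()
    pred = rt_norm.predict_rt(rt_model, entry.normalized_rt, run)
    lo, hi = pred - rt_half_window, pred + rt_half_window
    if hi < 0 or lo >= run.n_cycles:
        logger.warning(
            "predicted RT of %s outside the run; no candidates",
            entry.modified_sequence,
        )
        return []
    centers = np.arange(max(lo, 0), min(hi + 1, run.n_cycles))
    traces = _rsm.extract_precursor_traces(run, entry, params)
    aw = _rsm.assemble_windows(traces, centers, params)
    feats, dds = deep_rep.embed_batch(model, _rsm.normalize_matrices(aw.matrices))
    return _candidates_from_windows(aw, dds, feats, pred, dds_threshold)


def build_candidates(
    run: RunData,
    entries: list[LibraryEntry],
    rt_model: rt_norm.RTModel,
    model: deep_rep.RepresentationModel,
    params: _rsm.RSMParams | None = None,
    rt_half_window: int = DEFAULT_RT_HALF_WINDOW,
    dds_threshold: float = DEFAULT_DDS_THRESHOLD,
    chunk_size: int = 64,
) -> list[CandidatePeakGroup]:
    """Candidates for a whole library, with chunked batched embedding.

    Identical results to calling :func:`enumerate_candidates` per entry, but
    windows of many precursors are embedded in one forward pass.
    """
    params = params or _rsm.RSMParams()
    out: list[CandidatePeakGroup] = []
    for start in range(0, len(entries), chunk_size):
        chunk = entries[start:start + chunk_size]
        traces = _rsm.extract_traces_for_entries(run, chunk, params)
        assembled, preds = [], []
        for entry, tr in zip(chunk, traces):
            pred = rt_norm.predict_rt(rt_model, entry.normalized_rt, run)
            lo, hi = pred - rt_half_window, pred + rt_half_window
            if hi < 0 or lo >= run.n_cycles:
                logger.warning(
                    "predicted RT of %s outside the run; no candidates",
                    entry.modified_sequence,
                )
                continue
            centers = np.arange(max(lo, 0), min(hi + 1, run.n_cycles))
            assembled.append(_rsm.assemble_windows(tr, centers, params))
            preds.append(pred)
        if not assembled:
            continue
        mats = np.concatenate(
            [_rsm.normalize_matrices(aw.matrices).astype(np.float32)
             for aw in assembled]
        )
        feats, dds = deep_rep.embed_batch(model, mats)
        pos = 0
        for aw, pred in zip(assembled, preds):
            n = len(aw.centers)
            out.extend(_candidates_from_windows(
                aw, dds[pos:pos + n], feats[pos:pos + n], pred, dds_threshold
            ))
            pos += n
    return out


def _features_labels(candidates):
    X = np.array([c.feature_vector() for c in candidates])
    y = np.array([0 if c.is_decoy else 1 for c in candidates])
    return X, y


def train_pu_classifier(
    candidates: list[CandidatePeakGroup],
    model_type: str = "xgboost",
    seed: int = 0,
):
    """Fit the run-specific PU classifier on all candidate feature vectors."""
    X, y = _features_labels(candidates)
    if (y == 0).sum() == 0:
        raise ValueError("no decoy candidates; cannot calibrate the classifier")
    if (y == 1).sum() == 0:
        raise ValueError("no target candidates; nothing to learn from")
    if model_type == "xgboost":
        from xgboost import XGBClassifier
        clf = XGBClassifier(
            max_depth=6, n_estimators=100, learning_rate=0.3,
            random_state=seed, n_jobs=1, verbosity=0,
            eval_metric="logloss",
        )
    elif model_type == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        clf = RandomForestClassifier(
            max_depth=12, n_estimators=200, random_state=seed, n_jobs=1
        )
    else:
        raise ValueError(
            f"model_type must be 'xgboost' or 'random_forest', got {model_type!r}"
        )
    clf.fit(X, y)
    return clf


def score_candidates(candidates, classifier) -> None:
    """Attach the classifier's target probability to every candidate."""
    X, _ = _features_labels(candidates)
    scores = classifier.predict_proba(X)[:, 1]
    for c, s in zip(candidates, scores):
        c.discriminant_score = float(s)


def cross_score_candidates(
    candidates: list[CandidatePeakGroup],
    model_type: str = "xgboost",
    seed: int = 0,
    n_folds: int = 2,
) -> None:
    """Fold-based PU scoring: every candidate is scored by a classifier that
    never saw its precursor.

    Precursors (targets and decoys independently) are assigned whole to one
    of ``n_folds`` folds; each fold is scored by the classifier trained on
    the others. This removes the self-scoring bias a single train/score pass
    on high-cardinality features (e.g. precursor m/z) would introduce.
    ``n_folds=1`` reproduces the single-pass scheme.
    """
    if n_folds <= 1:
        clf = train_pu_classifier(candidates, model_type, seed)
        score_candidates(candidates, clf)
        return
    keys = sorted({
        (c.entry.modified_sequence, c.entry.precursor_charge, c.is_decoy)
        for c in candidates
    })
    rng = np.random.default_rng(seed)
    fold_of = dict(zip(keys, rng.integers(0, n_folds, len(keys))))
    folds = np.array([
        fold_of[(c.entry.modified_sequence, c.entry.precursor_charge, c.is_decoy)]
        for c in candidates
    ])
    for f in range(n_folds):
        held_out = np.flatnonzero(folds == f)
        train_set = [c for c, k in zip(candidates, folds) if k != f]
        if not held_out.size or not train_set:
            continue
        clf = train_pu_classifier(train_set, model_type, seed)
        X = np.array([candidates[i].feature_vector() for i in held_out])
        scores = clf.predict_proba(X)[:, 1]
        for i, s in zip(held_out, scores):
            candidates[i].discriminant_score = float(s)


def score_and_select(
    candidates: list[CandidatePeakGroup], classifier=None
) -> list[ScoredResult]:
    """Best candidate per precursor (targets and decoys alike).

    Ties break toward the candidate closer to the predicted RT, then the
    earlier cycle. Decoys are retained — they carry the FDR estimate.
    """
    if classifier is not None:
        score_candidates(candidates, classifier)
    if any(c.discriminant_score is None for c in candidates):
        raise ValueError("candidates must be scored before selection")
    best: dict = {}
    for c in candidates:
        key = (c.entry.modified_sequence, c.entry.precursor_charge, c.is_decoy)
        rank = (-c.discriminant_score, c.rt_deviation, c.center_cycle)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, c)
    return [
        ScoredResult(entry=c.entry, candidate=c,
                     discriminant_score=c.discriminant_score)
        for _, c in best.values()
    ]


def estimate_fdr(
    results: list[ScoredResult], level: str = "precursor"
) -> list[ScoredResult]:
    """Assign monotonized target-decoy q-values.

    FDR(c) = #decoys(score >= c) / max(1, #targets(score >= c)); the q-value
    of a result is the minimum FDR over all cutoffs at or below its score.
    Protein level groups results by protein, scored by the best member.
    """
    targets = [r for r in results if not r.is_decoy]
    decoys = [r for r in results if r.is_decoy]
    if not targets:
        raise ValueError("no target results; cannot estimate FDR")

    if level == "precursor":
        _assign_q(results)
        return results
    if level == "protein":
        groups: dict[tuple[str, bool], float] = {}
        for r in results:
            key = (r.entry.protein_id, r.is_decoy)
            groups[key] = max(groups.get(key, -np.inf), r.discriminant_score)
        items = sorted(groups.items(), key=lambda kv: -kv[1])
        scores = np.array([s for _, s in items])
        is_dec = np.array([k[1] for k, _ in items])
        q = _q_from_sorted(scores, is_dec)
        qmap = {k: qi for (k, _), qi in zip(items, q)}
        for r in results:
            r.q_value = float(qmap[(r.entry.protein_id, r.is_decoy)])
        return results
    raise ValueError(f"level must be 'precursor' or 'protein', got {level!r}")


def _q_from_sorted(scores_desc: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values for results already sorted by descending score.

    Ties share a cutoff: counts are taken at the last index of each tie run.
    """
    n = len(scores_desc)
    dec_cum = np.cumsum(is_decoy)
    tgt_cum = np.cumsum(~is_decoy)
    # index of the last element with the same score (>= cutoff includes ties)
    last_of_tie = np.searchsorted(-scores_desc, -scores_desc, side="right") - 1
    fdr = dec_cum[last_of_tie] / np.maximum(tgt_cum[last_of_tie], 1)
    return np.minimum.accumulate(fdr[::-1])[::-1]


def _assign_q(results: list[ScoredResult]) -> None:
    order = sorted(range(len(results)),
                   key=lambda i: -results[i].discriminant_score)
    scores = np.array([results[i].discriminant_score for i in order])
    is_dec = np.array([results[i].is_decoy for i in order])
    q = _q_from_sorted(scores, is_dec)
    for i, qi in zip(order, q):
        results[i].q_value = float(qi)
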