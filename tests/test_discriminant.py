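"""Candidate enumeration, PU rescoring, selection, FDR estimation."""

import numpy as np
import pytest

from diaxic import discriminant, rt_norm, synth
from diaxic.discriminant import (
    CandidatePeakGroup, ScoredResult, enumerate_candidates, estimate_fdr,
    score_and_select, train_pu_classifier,
)
from diaxic.speclib import FragmentIon, LibraryEntry


def _unique_seq(i, prefix="PEPT"):
    """Digit-free unique peptide sequence for stub entries."""
    code = "".join("ACDEFGHILM"[int(d)] for d in f"{i:03d}")
    return f"{prefix}{code}K"


def _stub_entry(seq="PEPTIDEK", decoy=False, protein="P1"):
    return LibraryEntry(seq, 450.0, 2, 10.0,
                        [FragmentIon("y3", 375.0, 1, 5.0)], protein,
                        is_decoy=decoy)


def _stub_candidate(entry, score=None, dds=0.7, rt_dev=0.0, center=10,
                    rng=None, offset=0.0):
    rng = rng or np.random.default_rng(0)
    aux = np.array([entry.precursor_mz, entry.precursor_charge,
                    entry.peptide_length, rt_dev, 3.0, 5.0])
    c = CandidatePeakGroup(
        entry=entry, center_cycle=center, dds=dds,
        deep_features=rng.random(16) + offset, aux_features=aux,
    )
    c.discriminant_score = score
    return c


@pytest.fixture(scope="module")
def rt_setup(small_model):
    cfg = synth.SynthConfig(n_precursors=80, seed=17)
    exp = synth.generate_experiment(cfg)
    anchors = rt_norm.select_anchors(exp.run, exp.library, small_model,
                                     n_sample=50, seed=1)
    rtm = rt_norm.fit_rt_model(anchors, "linear", seed=1)
    return exp, rtm


class TestEnumeration:
    def test_impossible_threshold_leaves_single_fallback(self, rt_setup, small_model):
        exp, rtm = rt_setup
        cands = enumerate_candidates(
            exp.run, exp.library[0], rtm, small_model, dds_threshold=1.0
        )
        assert len(cands) == 1

    def test_zero_threshold_yields_full_window(self, rt_setup, small_model):
        exp, rtm = rt_setup
        # pick a precursor eluting mid-gradient so the window fits inside
        mid = min(exp.library, key=lambda e: abs(e.normalized_rt - 50.0))
        w = 10
        cands = enumerate_candidates(
            exp.run, mid, rtm, small_model, rt_half_window=w, dds_threshold=0.0
        )
        assert len(cands) == 2 * w + 1

    def test_candidates_cover_true_apex(self, rt_setup, small_model):
        exp, rtm = rt_setup
        apex = dict(zip(exp.truth.modified_sequence, exp.truth.apex_cycle))
        found = 0
        for e in exp.library[:10]:
            cands = enumerate_candidates(exp.run, e, rtm, small_model)
            centers = {c.center_cycle for c in cands}
            found += apex[e.modified_sequence] in centers
        assert found >= 9

    def test_batched_equals_per_entry(self, rt_setup, small_model):
        exp, rtm = rt_setup
        entries = exp.library[:4]
        batched = discriminant.build_candidates(
            exp.run, entries, rtm, small_model, chunk_size=2
        )
        solo = []
        for e in entries:
            solo.extend(enumerate_candidates(exp.run, e, rtm, small_model))
        assert len(batched) == len(solo)
        for a, b in zip(batched, solo):
            assert a.center_cycle == b.center_cycle
            assert a.dds == pytest.approx(b.dds, abs=1e-5)
            assert np.allclose(a.deep_features, b.deep_features, atol=1e-4)

    def test_aux_features_are_finite(self, rt_setup, small_model):
        exp, rtm = rt_setup
        cands = enumerate_candidates(exp.run, exp.library[0], rtm, small_model)
        for c in cands:
            assert np.all(np.isfinite(c.aux_features))
            assert 0.0 < c.dds < 1.0
            assert c.feature_vector().shape == (23,)


class TestPUClassifier:
    def _separable_candidates(self, n=200):
        rng = np.random.default_rng(1)
        out = []
        for i in range(n):
            decoy = i % 2 == 1
            e = _stub_entry(_unique_seq(i), decoy=decoy)
            out.append(_stub_candidate(
                e, dds=0.2 if decoy else 0.8, rng=rng,
                offset=0.0 if decoy else 2.0,
            ))
        return out

    def test_separable_features_reach_high_auc(self):
        from sklearn.metrics import roc_auc_score

        cands = self._separable_candidates()
        clf = train_pu_classifier(cands, "xgboost", seed=0)
        X = np.array([c.feature_vector() for c in cands])
        y = np.array([0 if c.is_decoy else 1 for c in cands])
        assert roc_auc_score(y, clf.predict_proba(X)[:, 1]) > 0.95

    @pytest.mark.parametrize("model_type", ["xgboost", "random_forest"])
    def test_same_seed_same_scores(self, model_type):
        cands = self._separable_candidates(80)
        X = np.array([c.feature_vector() for c in cands])
        s = []
        for _ in range(2):
            clf = train_pu_classifier(cands, model_type, seed=7)
            s.append(clf.predict_proba(X)[:, 1])
        assert np.array_equal(s[0], s[1])

    def test_all_target_input_rejected(self):
        cands = [_stub_candidate(_stub_entry(f"PEPTID{c}K"))
                 for c in "AEST"]
        with pytest.raises(ValueError, match="decoy"):
            train_pu_classifier(cands)

    def test_unknown_model_type(self):
        with pytest.raises(ValueError, match="model_type"):
            train_pu_classifier(self._separable_candidates(10), "svm")

    def test_cross_scoring_never_self_scores(self):
        """With 2 folds every candidate gets a score and scores differ from
        the single-pass (self-scored) scheme."""
        cands = self._separable_candidates(100)
        discriminant.cross_score_candidates(cands, seed=0, n_folds=2)
        cv = [c.discriminant_score for c in cands]
        assert all(s is not None for s in cv)
        discriminant.cross_score_candidates(cands, seed=0, n_folds=1)
        sp = [c.discriminant_score for c in cands]
        assert not np.allclose(cv, sp)


class TestSelection:
    def test_max_score_candidate_retained(self):
        e = _stub_entry()
        cands = [_stub_candidate(e, score=s, center=i)
                 for i, s in enumerate((0.2, 0.9, 0.4))]
        (res,) = score_and_select(cands)
        assert res.discriminant_score == 0.9
        assert res.candidate.center_cycle == 1

    def test_tie_breaks_toward_predicted_rt_then_earlier_cycle(self):
        e = _stub_entry()
        cands = [
            _stub_candidate(e, score=0.8, rt_dev=5.0, center=3),
            _stub_candidate(e, score=0.8, rt_dev=1.0, center=9),
            _stub_candidate(e, score=0.8, rt_dev=1.0, center=7),
        ]
        (res,) = score_and_select(cands)
        assert res.candidate.center_cycle == 7

    def test_decoys_retained_in_output(self):
        t, d = _stub_entry(), _stub_entry("KEDITPEP", decoy=True)
        res = score_and_select([
            _stub_candidate(t, score=0.9), _stub_candidate(d, score=0.3),
        ])
        assert sorted(r.is_decoy for r in res) == [False, True]

    def test_unscored_candidates_rejected(self):
        with pytest.raises(ValueError, match="scored"):
            score_and_select([_stub_candidate(_stub_entry())])


def _results(target_scores, decoy_scores, protein="P1"):
    out = []
    for i, s in enumerate(target_scores):
        e = _stub_entry(_unique_seq(i, "PEPTQ"), protein=f"{protein}_{i}")
        out.append(ScoredResult(e, _stub_candidate(e, score=s), s))
    for i, s in enumerate(decoy_scores):
        e = _stub_entry(_unique_seq(i, "QTPEP"), decoy=True,
                        protein=f"DECOY_{protein}_{i}")
        out.append(ScoredResult(e, _stub_candidate(e, score=s), s))
    return out


class TestFDR:
    def test_hand_enumerated_estimator(self):
        res = estimate_fdr(_results([0.9, 0.8, 0.7], [0.75]))
        by_score = {r.discriminant_score: r.q_value for r in res
                    if not r.is_decoy}
        assert by_score[0.9] == 0.0
        assert by_score[0.8] == 0.0
        assert by_score[0.7] == pytest.approx(1 / 3)

    def test_no_decoy_above_top_target(self):
        res = estimate_fdr(_results([0.99], [0.5, 0.4]))
        top = [r for r in res if not r.is_decoy][0]
        assert top.q_value == 0.0

    def test_q_values_monotone_in_score(self, rng):
        res = estimate_fdr(
            _results(rng.random(50).tolist(), rng.random(50).tolist())
        )
        ordered = sorted(res, key=lambda r: -r.discriminant_score)
        qs = [r.q_value for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError, match="target"):
            estimate_fdr(_results([], [0.5]))

    def test_protein_level_uses_best_member(self):
        e1 = _stub_entry("PEPTAAAK", protein="PX")
        e2 = _stub_entry("PEPTCCCK", protein="PX")
        d = _stub_entry("QQPEPTDK", decoy=True, protein="DECOY_PX")
        res = [
            ScoredResult(e1, _stub_candidate(e1, score=0.9), 0.9),
            ScoredResult(e2, _stub_candidate(e2, score=0.2), 0.2),
            ScoredResult(d, _stub_candidate(d, score=0.5), 0.5),
        ]
        estimate_fdr(res, level="protein")
        # both PX precursors share the protein q-value from the 0.9 cutoff
        assert res[0].q_value == res[1].q_value == 0.0
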