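import numpy as np
import pytest

from exprkit import NucSeq, ProtSeq, SequenceError
from exprkit.fixtures import sp_training_set
from exprkit.signal_peptide import (N_MODELS, SPScoreSet, WeightMatrix,
                                    WM_WIDTH, c_score_series, candidate_positions,
                                    cleavage_site, combine_scores,
                                    extract_features, load_ensemble, predict,
                                    save_ensemble, secondary_tier,
                                    train_ensemble)


class TestFeatures:
    def test_poly_a_homopolymer(self):
        v = extract_features(ProtSeq("A" * 30))
        assert v[0] == 1.0          # fully hydrophobic composition
        assert v[6] == 0.0          # net charge of first 5
        assert v[7] == 1.0          # hydrophobic run spans the window

    def test_charged_prefix(self):
        v = extract_features(ProtSeq("KKKKK" + "A" * 25))
        assert v[6] == 5.0

    def test_deterministic(self):
        p = ProtSeq("MKWVTFISLLFLFSSAYSRGV")
        assert np.array_equal(extract_features(p), extract_features(p))

    def test_short_sequence_padded(self):
        v = extract_features(ProtSeq("MKVLF"))
        assert np.all(np.isfinite(v))


class TestWeightMatrix:
    def test_zero_matrix_scores_flat(self):
        wm = WeightMatrix(np.zeros((20, WM_WIDTH)), np.full(20, 0.05))
        seq = "MKWVTFISLLFLFSSAYSRGVFRRD"
        scores = {p: wm.score(seq, p) for p in range(10, 20)}
        assert set(scores.values()) == {0.0}

    def test_ala_fixed_at_minus_one_dominates_column(self):
        rng = np.random.default_rng(0)
        sites = []
        for _ in range(200):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
            p = 20
            seq = seq[:p - 1] + "A" + seq[p:]  # Ala at position -1
            sites.append((seq, p))
        wm = WeightMatrix.from_sites(sites, [s for s, _ in sites])
        minus_one_col = wm.log_odds[:, 14]  # column for position -1
        assert np.argmax(minus_one_col) == "ACDEFGHIKLMNPQRSTVWY".index("A")

    def test_idealised_matrix_argmax_at_planted_site(self):
        # mass on Ala at -3 and -1: A-X-A motif scoring
        lo = np.zeros((20, WM_WIDTH))
        a = "ACDEFGHIKLMNPQRSTVWY".index("A")
        lo[a, 12] = 5.0  # position -3
        lo[a, 14] = 5.0  # position -1
        wm = WeightMatrix(lo, np.full(20, 0.05))
        seq = "M" + "K" * 10 + "L" * 8 + "AQA" + "D" * 20
        planted = 22  # cleavage after the final A of A-Q-A
        pos = candidate_positions(len(seq))
        scores = [wm.score(seq, int(p)) for p in pos]
        assert int(pos[int(np.argmax(scores))]) == planted

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            WeightMatrix(np.zeros((20, 5)), np.full(20, 0.05))


class TestCombineScores:
    def test_geometric_mean_example(self):
        s = np.array([0.64] * 5)
        c = np.full((5, 4), 0.25)
        y, final = combine_scores(s, c)
        assert np.allclose(y, 0.4)
        assert final == pytest.approx(0.4)

    def test_all_ones(self):
        y, final = combine_scores(np.ones(5), np.ones((5, 3)))
        assert final == 1.0

    def test_median_of_five(self):
        s = np.array([0.1, 0.2, 0.3, 0.4, 0.5]) ** 2
        c = np.ones((5, 2))
        y, final = combine_scores(s, c)
        assert final == pytest.approx(0.3)

    def test_identity_on_random_scoresets(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            s = rng.random(5)
            c = rng.random((5, 8))
            y, final = combine_scores(s, c)
            assert np.allclose(y, np.sqrt(s * c.max(axis=1)))
            assert final == np.median(y)


def _scoreset(c_scores, final=0.9, theta=0.5):
    c = np.asarray(c_scores, dtype=float)
    return SPScoreSet(
        s_scores=np.ones(5), c_scores=c,
        positions=np.arange(10, 10 + c.shape[1]),
        y_scores=np.ones(5), final_score=final, theta=theta,
        sp_detected=True, cleavage_pos=None,
    )


class TestCleavageSite:
    def test_median_of_maxima_selects_model(self):
        c = np.zeros((5, 6))
        for i, (m, pos) in enumerate(zip([0.2, 0.4, 0.6, 0.8, 0.9],
                                         [0, 1, 2, 3, 4])):
            c[i, pos] = m
        # median of maxima = 0.6 -> model 2, argmax at column 2
        assert cleavage_site(_scoreset(c)) == 12

    def test_identical_models_share_argmax(self):
        c = np.tile(np.array([0.1, 0.9, 0.2, 0.1, 0.0, 0.0]), (5, 1))
        assert cleavage_site(_scoreset(c)) == 11

    def test_tied_median_goes_to_lowest_model_index(self):
        c = np.zeros((5, 6))
        maxima = [0.2, 0.6, 0.6, 0.8, 0.9]
        argmaxes = [0, 1, 2, 3, 4]
        for i, (m, pos) in enumerate(zip(maxima, argmaxes)):
            c[i, pos] = m
        # median 0.6 attained by models 1 and 2: model 1 wins
        assert cleavage_site(_scoreset(c)) == 11

    def test_requires_detection(self):
        with pytest.raises(SequenceError):
            cleavage_site(_scoreset(np.ones((5, 3)), final=0.2))


class TestSecondaryTier:
    class _Stub:
        def __init__(self, p):
            self._p = p

        def predict_proba(self, X):
            return np.array([[1 - self._p, self._p]])

    def _ensemble(self, probs):
        from exprkit.signal_peptide import SPModelEnsemble
        wm = WeightMatrix(np.zeros((20, WM_WIDTH)), np.full(20, 0.05))
        stubs = [self._Stub(p) for p in probs]
        return SPModelEnsemble(stubs, stubs, wm, theta=0.5, tier="toxin")

    def test_median_and_star_count(self):
        score, stars = secondary_tier(ProtSeq("M" + "A" * 30),
                                      self._ensemble([0.9, 0.8, 0.7, 0.2, 0.1]))
        assert score == pytest.approx(0.7)
        assert stars == 3

    @pytest.mark.parametrize("probs,score,stars", [
        ([0.0] * 5, 0.0, 0), ([1.0] * 5, 1.0, 5)])
    def test_extremes(self, probs, score, stars):
        got = secondary_tier(ProtSeq("M" + "A" * 30), self._ensemble(probs))
        assert got == (score, stars)

    def test_requires_primary_detection(self):
        with pytest.raises(SequenceError):
            secondary_tier(ProtSeq("MAAA"), self._ensemble([1.0] * 5),
                           primary_fired=False)


class TestTraining:
    def test_requires_minimum_class_sizes(self):
        small = sp_training_set(100, seed=1)
        with pytest.raises(ValueError, match=">= 100"):
            train_ensemble(small)

    def test_retraining_is_deterministic(self, small_ensemble):
        again = train_ensemble(sp_training_set(300, seed=17), seed=17)
        probes, _ = zip(*[(p, y) for p, y, _ in sp_training_set(20, seed=99)])
        for p in probes:
            r1 = predict(p, small_ensemble)
            r2 = predict(p, again)
            assert np.array_equal(r1.s_scores, r2.s_scores)
            assert np.array_equal(r1.c_scores, r2.c_scores)

    def test_separable_features_reach_perfect_training_auc(self, small_ensemble):
        from sklearn.metrics import roc_auc_score
        data = sp_training_set(200, seed=31)
        from exprkit.signal_peptide import extract_features
        X = np.vstack([extract_features(p) for p, _, _ in data])
        y = np.array([lab for _, lab, _ in data])
        for m in small_ensemble.s_models:
            assert roc_auc_score(y, m.predict_proba(X)[:, 1]) >= 0.99


class TestPredict:
    def test_scoreset_identities_hold(self, small_ensemble):
        prot, _, _ = sp_training_set(4, seed=55)[0]
        r = predict(prot, small_ensemble)
        assert np.allclose(r.y_scores,
                           np.sqrt(r.s_scores * r.c_scores.max(axis=1)))
        assert r.final_score == np.median(r.y_scores)
        assert r.c_scores.shape == (N_MODELS, len(r.positions))

    def test_planted_sp_recovered_with_cleavage(self, small_ensemble):
        data = [t for t in sp_training_set(40, seed=77) if t[1] == 1]
        hits = 0
        for prot, _, cp in data:
            r = predict(prot, small_ensemble)
            assert r.final_score >= 0.5
            if r.cleavage_pos is not None and abs(r.cleavage_pos - cp) <= 2:
                hits += 1
        assert hits / len(data) >= 0.8

    def test_mature_like_sequence_not_called(self, small_ensemble):
        neg = ProtSeq("M" + "DE" * 20)  # charged, no h-region
        r = predict(neg, small_ensemble)
        assert r.final_score < 0.5
        assert r.cleavage_pos is None

    def test_nucleotide_input_translated(self, small_ensemble):
        prot, _, _ = sp_training_set(4, seed=3)[0]
        from exprkit.fixtures import child_rng, _back_translate
        cds = NucSeq(_back_translate(child_rng(1, "bt"), prot.residues))
        r_nuc = predict(cds, small_ensemble)
        r_prot = predict(prot, small_ensemble)
        assert r_nuc.final_score == r_prot.final_score

    def test_too_short_errors(self, small_ensemble):
        with pytest.raises(SequenceError):
            predict(ProtSeq("MKVLF"), small_ensemble)

    def test_tier_gating(self, small_ensemble):
        toxin = train_ensemble(
            sp_training_set(200, seed=5), tier="toxin", seed=5)
        neg = ProtSeq("M" + "DE" * 20)
        r = predict(neg, small_ensemble, toxin=toxin)
        if not r.sp_detected:
            assert r.toxin_score is None
        pos = [t for t in sp_training_set(10, seed=21) if t[1] == 1][0][0]
        r2 = predict(pos, small_ensemble, toxin=toxin)
        assert r2.sp_detected and r2.toxin_score is not None
        assert "toxin" in r2.stars


def test_save_load_round_trip(tmp_path, small_ensemble):
    save_ensemble(small_ensemble, tmp_path / "euk")
    loaded = load_ensemble(tmp_path / "euk")
    prot, _, _ = sp_training_set(4, seed=19)[0]
    r1, r2 = predict(prot, small_ensemble), predict(prot, loaded)
    assert r1.final_score == r2.final_score
    assert (tmp_path / "euk" / "manifest.json").exists()
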