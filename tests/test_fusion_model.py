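"""Two-step fused classifier: calibration, scoring, θ decision, OvR fusion."""

import numpy as np
import pandas as pd
import pytest

from mnalci.constants import CANCER_CLASSES
from mnalci.fusion_model import (
    CANCER,
    HEALTHY,
    AlignmentError,
    BinaryFusionModel,
    LinearSigmoidModel,
    MnalciScore,
    MulticlassFusionModel,
    ThresholdPolicy,
    argmax_class,
    classify_binary,
    cross_validate_5x5,
    fit_binary,
    fit_multiclass_ovr,
    fuse_and_predict,
    majority_vote,
    mnalci_score,
    predict_two_step,
)


def paired_features(rng, n=60, p=6, shift=4.0, informative=(0,)):
    """Aligned GNS/SiNW feature frames with a separable binary signal."""
    ids = [f"s{i}" for i in range(n)]
    y = np.array([HEALTHY] * (n // 2) + [CANCER] * (n - n // 2))
    frames = {}
    for tag in ("GNS", "SiNW"):
        X = rng.normal(size=(n, p))
        for j in informative:
            X[y == CANCER, j] += shift
        frames[tag] = pd.DataFrame(X, index=ids)
    return frames["GNS"], frames["SiNW"], y


class TestBinaryFusion:
    def test_separable_data_classified_perfectly(self, rng):
        X_gns, X_sinw, y = paired_features(rng, shift=8.0)
        model = fit_binary(X_gns, X_sinw, y, seed=0)
        scores = model.scores({"GNS": X_gns, "SiNW": X_sinw})
        preds = [classify_binary(s, ThresholdPolicy(1.0)) for s in scores]
        assert (np.array(preds) == y).all()

    def test_null_labels_give_chance_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        aucs = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            X_gns, X_sinw, y = paired_features(local, n=120, shift=0.0)
            perm = local.permutation(len(y))
            y = y[perm]
            train, test = np.arange(80), np.arange(80, 120)
            model = fit_binary(X_gns.iloc[train], X_sinw.iloc[train], y[train], seed=seed)
            s = model.scores({"GNS": X_gns.iloc[test], "SiNW": X_sinw.iloc[test]})
            aucs.append(roc_auc_score(y[test] == CANCER, s))
        assert 0.4 < float(np.mean(aucs)) < 0.6

    def test_same_seed_reproduces_parameters(self, rng):
        X_gns, X_sinw, y = paired_features(rng)
        m1 = fit_binary(X_gns, X_sinw, y, seed=3)
        m2 = fit_binary(X_gns, X_sinw, y, seed=3)
        for tag in ("GNS", "SiNW"):
            w1, b1 = m1.linear_params(tag)
            w2, b2 = m2.linear_params(tag)
            np.testing.assert_array_equal(w1, w2)
            assert b1 == b2

    def test_misaligned_sample_ids_rejected(self, rng):
        X_gns, X_sinw, y = paired_features(rng)
        X_sinw = X_sinw.rename(index={"s0": "weird"})
        with pytest.raises(AlignmentError, match="s0"):
            fit_binary(X_gns, X_sinw, y)

    def test_json_roundtrip_preserves_probabilities(self, rng, tmp_path):
        X_gns, X_sinw, y = paired_features(rng)
        model = fit_binary(X_gns, X_sinw, y, seed=0)
        path = tmp_path / "binary.json"
        model.to_json(path)
        back = BinaryFusionModel.from_json(path)
        feats = {"GNS": X_gns, "SiNW": X_sinw}
        pd.testing.assert_frame_equal(
            back.probabilities(feats), model.probabilities(feats), atol=1e-12
        )


class TestMnalciScore:
    def test_printed_fusion_example(self):
        score = mnalci_score(0.998, 0.988)
        assert score.value == pytest.approx(1.986, abs=1e-12)

    def test_bounds_attained(self):
        assert mnalci_score(0.0, 0.0).value == 0.0
        assert mnalci_score(1.0, 1.0).value == 2.0

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            mnalci_score(1.2, 0.5)
        with pytest.raises(ValueError, match="missing"):
            mnalci_score(float("nan"), 0.5)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            MnalciScore(2.5)


class TestThresholdDecision:
    def test_worked_example_called_cancer(self):
        assert classify_binary(mnalci_score(0.998, 0.988), ThresholdPolicy(1.0)) == CANCER

    def test_boundary_score_equal_theta_is_cancer(self):
        assert classify_binary(MnalciScore(1.0), ThresholdPolicy(1.0)) == CANCER

    def test_extreme_theta(self):
        policy = ThresholdPolicy(2.0)
        assert classify_binary(MnalciScore(2.0), policy) == CANCER
        assert classify_binary(MnalciScore(1.999), policy) == HEALTHY

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPolicy(2.5)
        with pytest.raises(ValueError):
            ThresholdPolicy(1.5, fusion=False)

    def test_decision_monotone_in_theta(self, rng):
        scores = rng.uniform(0, 2, 200)
        thetas = np.arange(0, 2.01, 0.1)
        prev_cancer = None
        for theta in thetas:
            cancer_set = {i for i, s in enumerate(scores) if classify_binary(MnalciScore(s), ThresholdPolicy(theta)) == CANCER}
            if prev_cancer is not None:
                assert cancer_set <= prev_cancer  # raising θ never adds a cancer call
            prev_cancer = cancer_set


def six_cluster_features(rng, n_per_class=14, p=12, shift=6.0):
    ids, labels, rows = [], [], []
    for c, cls in enumerate(CANCER_CLASSES):
        X = rng.normal(size=(n_per_class, p))
        X[:, 2 * c] += shift
        rows.append(X)
        labels += [cls] * n_per_class
        ids += [f"{cls}{i}" for i in range(n_per_class)]
    X = np.vstack(rows)
    return (
        pd.DataFrame(X, index=ids),
        pd.DataFrame(X + rng.normal(0, 0.1, X.shape), index=ids),
        np.array(labels),
    )


class TestMulticlassFusion:
    def test_separable_clusters_high_holdout_accuracy(self, rng):
        X_gns, X_sinw, y = six_cluster_features(rng)
        train = np.array([i % 3 != 0 for i in range(len(y))])
        model = fit_multiclass_ovr(X_gns.loc[train], X_sinw.loc[train], y[train], seed=0)
        preds, fused = fuse_and_predict(
            model, {"GNS": X_gns.loc[~train], "SiNW": X_sinw.loc[~train]}
        )
        assert (preds.to_numpy() == y[~train]).mean() > 0.95
        per_matrix = model.class_probabilities({"GNS": X_gns, "SiNW": X_sinw})
        for frame in per_matrix.values():
            assert ((frame.to_numpy() >= 0) & (frame.to_numpy() <= 1)).all()
        assert (fused.to_numpy() >= 0).all() and (fused.to_numpy() <= 2).all()

    def test_missing_class_rejected(self, rng):
        X_gns, X_sinw, y = six_cluster_features(rng)
        y = np.where(y == "PTC", "GC", y)
        with pytest.raises(ValueError, match="PTC"):
            fit_multiclass_ovr(X_gns, X_sinw, y)

    def test_seed_determinism(self, rng):
        X_gns, X_sinw, y = six_cluster_features(rng, n_per_class=8)
        m1 = fit_multiclass_ovr(X_gns, X_sinw, y, seed=1)
        m2 = fit_multiclass_ovr(X_gns, X_sinw, y, seed=1)
        feats = {"GNS": X_gns, "SiNW": X_sinw}
        pd.testing.assert_frame_equal(m1.fused_scores(feats), m2.fused_scores(feats))

    def test_json_roundtrip(self, rng, tmp_path):
        X_gns, X_sinw, y = six_cluster_features(rng, n_per_class=8)
        model = fit_multiclass_ovr(X_gns, X_sinw, y, seed=1)
        model.to_json(tmp_path / "m.json")
        back = MulticlassFusionModel.from_json(tmp_path / "m.json")
        feats = {"GNS": X_gns, "SiNW": X_sinw}
        pd.testing.assert_frame_equal(
            back.fused_scores(feats), model.fused_scores(feats), atol=1e-12
        )


def vec(**kw):
    out = {cls: 0.01 for cls in CANCER_CLASSES}
    out.update(kw)
    return out


class TestWorkedExamples:
    """The printed multiclass cases, replayed as decision logic."""

    def fuse(self, gns, sinw):
        return {c: gns[c] + sinw[c] for c in CANCER_CLASSES}

    def test_both_single_models_correct(self):
        gns, sinw = vec(HCC=0.998), vec(HCC=0.988)
        fused = self.fuse(gns, sinw)
        assert argmax_class(gns) == argmax_class(sinw) == argmax_class(fused) == "HCC"
        assert fused["HCC"] == pytest.approx(1.986)

    def test_fusion_rescues_gns_error(self):
        gns = vec(NSCLC=0.493, CRC=0.453)
        sinw = vec(CRC=0.652)
        fused = self.fuse(gns, sinw)
        assert argmax_class(gns) == "NSCLC"  # single model wrong
        assert argmax_class(sinw) == "CRC"
        assert argmax_class(fused) == "CRC"
        assert fused["CRC"] == pytest.approx(1.105)

    def test_fusion_rescues_sinw_error(self):
        gns = vec(HCC=0.904)
        sinw = vec(CRC=0.546, HCC=0.452)
        fused = self.fuse(gns, sinw)
        assert argmax_class(sinw) == "CRC"  # single model wrong
        assert argmax_class(fused) == "HCC"
        assert fused["HCC"] == pytest.approx(1.356)

    def test_fusion_follows_confident_error(self):
        gns = vec(GC=0.665, CRC=0.026)
        sinw = vec(CRC=0.928, GC=0.2)
        fused = self.fuse(gns, sinw)
        assert argmax_class(gns) == "GC"  # the correct single call is outvoted
        assert argmax_class(fused) == "CRC"
        assert fused["CRC"] == pytest.approx(0.954)

    def test_both_single_models_wrong(self):
        gns = vec(CRC=0.533)
        sinw = vec(GC=0.528, CRC=0.527)
        fused = self.fuse(gns, sinw)
        assert argmax_class(gns) == "CRC"
        assert argmax_class(sinw) == "GC"
        assert argmax_class(fused) == "CRC"
        assert fused["CRC"] == pytest.approx(1.060)

    def test_tie_breaks_by_fixed_class_order(self):
        fused = vec(NSCLC=0.8, GC=0.8)
        assert argmax_class(fused) == "NSCLC"  # NSCLC precedes GC in the fixed order
        conflict = self.fuse(vec(PAAD=1.0), vec(CRC=1.0))
        assert argmax_class(conflict) == "PAAD"  # equal confidence, order decides


class TestMajorityVote:
    def test_unanimous(self):
        out = majority_vote([{"A": 1.0}, {"A": 1.0}], ["A", "B"])
        assert out == "A"

    def test_split_vote_rejects(self):
        assert majority_vote([{"A": 1.0}, {"B": 1.0}], ["A", "B"]) is None

    def test_two_of_three(self):
        assert majority_vote([{"A": 1.0}, {"A": 1.0}, {"B": 1.0}], ["A", "B"]) == "A"

    def test_no_members_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([], ["A"])


class TestCrossValidation:
    def test_single_grid_point_returned(self, rng):
        X_gns, X_sinw, y = paired_features(rng, n=50, shift=5.0)
        best_C, err, model = cross_validate_5x5(X_gns, X_sinw, y, C_grid=[1.0], seed=0)
        assert best_C == 1.0
        assert 0.0 <= err <= 1.0
        assert isinstance(model, BinaryFusionModel)

    def test_empty_grid_rejected(self, rng):
        X_gns, X_sinw, y = paired_features(rng, n=30)
        with pytest.raises(ValueError):
            cross_validate_5x5(X_gns, X_sinw, y, C_grid=[])

    def test_mean_error_matches_naive_loop(self, rng):
        """CV error agrees with a hand-rolled 25-run loop within sampling noise."""
        from sklearn.model_selection import StratifiedKFold

        X_gns, X_sinw, y = paired_features(rng, n=60, p=4, shift=1.2)
        _, err, _ = cross_validate_5x5(X_gns, X_sinw, y, C_grid=[1.0], seed=0)
        naive_errors = []
        policy = ThresholdPolicy(1.0)
        for repeat in range(5):
            cv = StratifiedKFold(5, shuffle=True, random_state=100 + repeat)
            for train_idx, test_idx in cv.split(X_gns, y):
                model = fit_binary(X_gns.iloc[train_idx], X_sinw.iloc[train_idx], y[train_idx], seed=repeat)
                s = model.scores({"GNS": X_gns.iloc[test_idx], "SiNW": X_sinw.iloc[test_idx]})
                preds = np.array([classify_binary(v, policy) for v in s])
                naive_errors.append(float((preds != y[test_idx]).mean()))
        assert abs(err - float(np.mean(naive_errors))) < 0.1


class TestTwoStep:
    def test_healthy_gate_then_tissue_of_origin(self, rng):
        X_gns, X_sinw, y6 = six_cluster_features(rng, n_per_class=8)
        # a shared malignancy axis separates every cancer from the controls
        X_gns.iloc[:, -1] += 5.0
        X_sinw.iloc[:, -1] += 5.0
        hc = pd.DataFrame(rng.normal(size=(10, X_gns.shape[1])), index=[f"HC{i}" for i in range(10)])
        Xg = pd.concat([X_gns, hc])
        Xs_ = pd.concat([X_sinw, hc])
        y = np.concatenate([np.full(len(y6), CANCER), np.full(10, HEALTHY)])
        binary = fit_binary(Xg, Xs_, y, seed=0)
        multi = fit_multiclass_ovr(X_gns, X_sinw, y6, seed=0)
        preds = predict_two_step(binary, multi, {"GNS": Xg, "SiNW": Xs_})
        assert (preds.loc[hc.index] == "HC").mean() > 0.8
        cancer_preds = preds.loc[X_gns.index]
        correct = (cancer_preds.to_numpy() == y6).mean()
        assert correct > 0.8
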