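"""Classifier ensemble, AUC, Rejection Scores and evaluation loops."""

import numpy as np
import pandas as pd
import pytest

from drugnet.classify import (
    ClassifierSpec,
    RotationForestClassifier,
    TrainingError,
    ablate_failure_reasons,
    auc,
    default_specs,
    predict_problematic_prob,
    rejection_score,
    repeated_holdout,
    rs_summary,
    score_candidates,
    train,
)
from drugnet.drugs import DrugRecord
from drugnet.features import FeatureMatrix
from drugnet.imbalance import PreprocessConfig

from .oracles import brute_auc


def matrix(X, y):
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])],
                      index=[f"D{i}" for i in range(len(X))])
    return FeatureMatrix(df, pd.Series(list(y), index=df.index))


def two_clusters(rng, n=20, sep=6.0):
    X = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(sep, 0.3, (n, 2))])
    y = ["approved"] * n + ["problematic"] * n
    return matrix(X, y)


class TestAuc:
    def test_perfect_ranking(self):
        assert auc(["approved", "problematic"], [0.1, 0.9]) == 1.0

    def test_all_tied_scores(self):
        assert auc(["approved", "problematic", "approved"], [0.5, 0.5, 0.5]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        labels = list(rng.choice(["approved", "problematic"], size=12))
        labels[0], labels[1] = "approved", "problematic"  # both classes present
        scores = list(np.round(rng.uniform(size=12), 1))  # rounding forces ties
        assert auc(labels, scores) == pytest.approx(
            brute_auc(labels, scores, "problematic")
        )

    def test_invariant_under_monotone_transform(self, rng):
        labels = ["approved"] * 6 + ["problematic"] * 6
        scores = rng.uniform(size=12)
        assert auc(labels, scores) == pytest.approx(auc(labels, np.exp(3 * scores)))

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            auc(["approved", "approved"], [0.1, 0.2])


class TestRejectionScore:
    def test_mean_of_components(self):
        assert rejection_score([0.9, 0.8, 1.0]).score == pytest.approx(0.9)

    def test_zero_components(self):
        assert rejection_score([0.0, 0.0, 0.0]).score == 0.0

    def test_permutation_invariance_and_bounds(self):
        probs = [0.2, 0.7, 0.4]
        s1 = rejection_score(probs).score
        s2 = rejection_score(probs[::-1]).score
        assert s1 == pytest.approx(s2)
        assert min(probs) <= s1 <= max(probs)

    def test_wrong_arity_or_range_rejected(self):
        with pytest.raises(ValueError):
            rejection_score([0.5, 0.5])
        with pytest.raises(ValueError):
            rejection_score([0.5, 0.5, 1.5])


class TestTrainPredict:
    @pytest.mark.parametrize("family", ["instance_based", "neural_net", "rotation_ensemble"])
    def test_separable_clusters_learned_perfectly(self, family, rng):
        m = two_clusters(rng)
        model = train(ClassifierSpec.make(family, seed=0), m)
        p = predict_problematic_prob(model, m)
        assert auc(m.labels.to_numpy(), p) == 1.0

    def test_single_class_training_is_error(self, rng):
        m = matrix(rng.uniform(size=(10, 2)), ["approved"] * 10)
        with pytest.raises(TrainingError):
            train(ClassifierSpec.make("instance_based"), m)

    def test_unknown_family_is_error(self, rng):
        with pytest.raises(TrainingError, match="registered"):
            train(ClassifierSpec.make("weka_j48"), two_clusters(rng))

    def test_deterministic_under_seed(self, rng):
        m = two_clusters(rng, sep=2.0)
        for family in ("neural_net", "rotation_ensemble"):
            spec = ClassifierSpec.make(family, seed=7)
            p1 = predict_problematic_prob(train(spec, m), m)
            p2 = predict_problematic_prob(train(spec, m), m)
            assert np.array_equal(p1, p2)

    def test_probabilities_bounded(self, rng):
        m = two_clusters(rng, sep=1.0)
        probe = matrix(rng.uniform(-10, 10, size=(200, 2)), ["approved"] * 200)
        for spec in default_specs(0):
            p = predict_problematic_prob(train(spec, m), probe)
            assert (p >= 0).all() and (p <= 1).all()

    def test_feature_mismatch_is_error(self, rng):
        m = two_clusters(rng)
        model = train(ClassifierSpec.make("instance_based"), m)
        other = matrix(rng.uniform(size=(3, 3)), ["approved"] * 3)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_problematic_prob(model, other)

    def test_instance_based_recalls_training_point(self, rng):
        m = two_clusters(rng, sep=4.0)
        model = train(ClassifierSpec.make("instance_based", seed=0), m)
        prob_idx = m.labels[m.labels == "problematic"].index[0]
        probe = FeatureMatrix(m.values.loc[[prob_idx]], m.labels.loc[[prob_idx]])
        assert predict_problematic_prob(model, probe)[0] >= 0.5


class TestRotationForest:
    def test_rotations_are_orthogonal(self, rng):
        m = two_clusters(rng)
        clf = RotationForestClassifier(n_estimators=5, random_state=0)
        clf.fit(m.values.to_numpy(), m.labels.to_numpy())
        for R in clf.rotations_:
            assert np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8)

    def test_predict_proba_rows_sum_to_one(self, rng):
        m = two_clusters(rng, sep=1.5)
        clf = RotationForestClassifier(random_state=1)
        clf.fit(m.values.to_numpy(), m.labels.to_numpy())
        p = clf.predict_proba(rng.uniform(size=(50, 2)))
        assert np.allclose(p.sum(axis=1), 1.0)


def make_drugs_and_raw(rng, n_app=30, n_prob=12, sep=4.0, reasons=("safety",)):
    drugs = []
    rows = {}
    for i in range(n_app):
        d = DrugRecord(f"A{i}", "approved", "approved", frozenset([f"PA{i}"]))
        drugs.append(d)
        rows[d.drug_id] = rng.normal(0, 1.0, 3)
    for i in range(n_prob):
        d = DrugRecord(f"B{i}", "withdrawn", "problematic", frozenset([f"PB{i}"]),
                       failure_reason=reasons[i % len(reasons)])
        drugs.append(d)
        rows[d.drug_id] = rng.normal(sep, 1.0, 3)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["f0", "f1", "f2"])
    labels = pd.Series({d.drug_id: d.label for d in drugs})
    return drugs, FeatureMatrix(df, labels)


FAST = PreprocessConfig(smote_percent=200, smote_k=3, misclassified_enabled=False)


class TestRepeatedHoldout:
    def test_report_shape(self, rng):
        drugs, raw = make_drugs_and_raw(rng)
        rep = repeated_holdout(drugs, raw, n_repeats=3, config=FAST, seed=0)
        assert len(rep.auc_values) == 3
        assert all(len(v) == 3 for v in rep.per_spec_auc.values())

    def test_separated_classes_high_auc(self, rng):
        drugs, raw = make_drugs_and_raw(rng, sep=5.0)
        rep = repeated_holdout(drugs, raw, n_repeats=3, config=FAST, seed=1)
        assert rep.mean_auc > 0.9

    def test_reproducible_under_seed(self, rng):
        drugs, raw = make_drugs_and_raw(rng, sep=1.0)
        a = repeated_holdout(drugs, raw, n_repeats=2, config=FAST, seed=3)
        b = repeated_holdout(drugs, raw, n_repeats=2, config=FAST, seed=3)
        assert a.auc_values == b.auc_values


class TestAblation:
    def test_one_report_per_reason(self, rng):
        drugs, raw = make_drugs_and_raw(rng, reasons=("safety", "efficacy"))
        reports = ablate_failure_reasons(drugs, raw, n_repeats=2, config=FAST, seed=0)
        assert set(reports) == {"safety", "efficacy"}

    def test_removing_noise_group_raises_auc(self, rng):
        # plant label noise: "withdrawn"-reason problematic drugs sit in the
        # approved cluster
        drugs, raw = make_drugs_and_raw(rng, n_app=40, n_prob=16, sep=4.0,
                                        reasons=("safety",))
        noisy = []
        rows = {}
        for i in range(8):
            d = DrugRecord(f"N{i}", "withdrawn", "problematic",
                           frozenset([f"PN{i}"]), failure_reason="withdrawn")
            noisy.append(d)
            rows[d.drug_id] = rng.normal(0, 1.0, 3)  # approved-like features
        df = pd.concat([raw.values,
                        pd.DataFrame.from_dict(rows, orient="index",
                                               columns=raw.values.columns)])
        labels = pd.concat([raw.labels,
                            pd.Series({d.drug_id: d.label for d in noisy})])
        all_drugs = drugs + noisy
        all_raw = FeatureMatrix(df, labels)
        baseline = repeated_holdout(all_drugs, all_raw, n_repeats=4, config=FAST, seed=5)
        reports = ablate_failure_reasons(all_drugs, all_raw, n_repeats=4,
                                         config=FAST, seed=5)
        assert reports["withdrawn"].mean_auc > baseline.mean_auc


class TestScoreCandidates:
    def test_candidate_near_problematic_cluster_scores_high(self, rng):
        drugs, raw = make_drugs_and_raw(rng, sep=5.0)
        cand = DrugRecord("C0", "investigational", "experimental",
                          frozenset(["PX"]))
        cand_raw = FeatureMatrix(
            pd.DataFrame([rng.normal(5.0, 0.1, 3)], index=["C0"],
                         columns=raw.values.columns),
            pd.Series({"C0": "experimental"}),
        )
        (score,) = score_candidates(drugs, [cand], raw, cand_raw,
                                    config=FAST, seed=0)
        assert score.score > 0.5
        assert len(score.component_probs) == 3

    def test_never_trains_on_matching_target_set(self, rng, monkeypatch):
        drugs, raw = make_drugs_and_raw(rng)
        cand = DrugRecord("C0", "investigational", "experimental", drugs[0].targets)
        cand_raw = FeatureMatrix(
            pd.DataFrame([rng.normal(0, 1, 3)], index=["C0"],
                         columns=raw.values.columns),
            pd.Series({"C0": "experimental"}),
        )
        seen = []
        import drugnet.classify as mod

        original = mod.preprocess

        def spy(train_m, cfg):
            seen.append(set(train_m.values.index))
            return original(train_m, cfg)

        monkeypatch.setattr(mod, "preprocess", spy)
        score_candidates(drugs, [cand], raw, cand_raw, config=FAST, seed=0)
        assert all(drugs[0].drug_id not in ids for ids in seen)


class TestRsSummary:
    def scores(self, vals, label):
        return [rejection_score([v, v, v], drug_id=f"{label}{i}")
                for i, v in enumerate(vals)], \
               {f"{label}{i}": label for i in range(len(vals))}

    def test_all_ones_full_percentages(self):
        s, labels = self.scores([1.0, 1.0], "approved")
        tab = rs_summary(s, labels, cutoffs=[0.5])
        assert tab.loc[0.5, "approved"] == 100.0

    def test_zero_cutoff_is_100_percent(self, rng):
        s, labels = self.scores(list(rng.uniform(size=5)), "approved")
        tab = rs_summary(s, labels, cutoffs=[0.0])
        assert tab.loc[0.0, "approved"] == 100.0

    def test_matches_counting_oracle_and_monotone(self, rng):
        vals_a = list(rng.uniform(size=20))
        vals_p = list(rng.uniform(size=10))
        sa, la = self.scores(vals_a, "approved")
        sp, lp = self.scores(vals_p, "problematic")
        cutoffs = [0.0, 0.25, 0.5, 0.75, 0.9]
        tab = rs_summary(sa + sp, {**la, **lp}, cutoffs)
        for c in cutoffs:
            assert tab.loc[c, "approved"] == pytest.approx(
                100 * sum(v >= c for v in vals_a) / 20
            )
        for col in tab.columns:
            assert (tab[col].diff().dropna() <= 0).all()

    def test_unsorted_cutoffs_rejected(self, rng):
        s, labels = self.scores([0.5], "approved")
        with pytest.raises(ValueError, match="sorted"):
            rs_summary(s, labels, cutoffs=[0.5, 0.1])
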