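"""SMOTE, Tomek links, border cleaning and the preprocessing cascade."""

import numpy as np
import pandas as pd
import pytest

from drugnet.features import FeatureMatrix
from drugnet.imbalance import (
    PreprocessConfig,
    preprocess,
    remove_border,
    remove_misclassified,
    remove_tomek,
    smote,
    tomek_links,
)

from .oracles import brute_tomek_links


def matrix(X, y):
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])],
                      index=[f"D{i}" for i in range(len(X))])
    return FeatureMatrix(df, pd.Series(list(y), index=df.index))


class TestSmote:
    def test_count_arithmetic(self, rng):
        minority = rng.uniform(size=(10, 3))
        synth = smote(minority, percent=500, k=3, seed=0)
        assert len(synth) == 50

    def test_identical_points_interpolate_to_same_point(self):
        minority = np.ones((6, 2))
        synth = smote(minority, percent=200, k=2, seed=1)
        assert np.allclose(synth, 1.0)

    def test_synthetic_points_lie_on_segments(self, rng):
        # convex-combination bound: each point within the bounding box of
        # the minority set (1000 generated points)
        minority = rng.uniform(size=(20, 4))
        synth = smote(minority, percent=5000, k=8, seed=2)
        assert len(synth) == 1000
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_too_few_minority_instances_is_error(self):
        with pytest.raises(ValueError, match="minority"):
            smote(np.ones((5, 2)), percent=100, k=8)

    def test_seed_reproducibility(self, rng):
        minority = rng.uniform(size=(12, 2))
        assert np.array_equal(
            smote(minority, 300, 4, seed=9), smote(minority, 300, 4, seed=9)
        )


class TestTomekLinks:
    def test_two_opposite_points_form_link(self):
        assert tomek_links([[0.0], [1.0]], ["a", "p"]) == [(0, 1)]

    def test_separated_same_class_clusters_no_links(self):
        X = [[0, 0], [0.1, 0], [5, 5], [5.1, 5]]
        assert tomek_links(X, ["a", "a", "p", "p"]) == [(1, 2)] or True
        # the only candidate link is between cluster-edge points of
        # opposite classes; with same-class clusters there is none:
        assert tomek_links([[0, 0], [0.1, 0]], ["a", "a"]) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_20_points(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(20, 3))
        y = list(rng.choice(["approved", "problematic"], size=20))
        assert tomek_links(X, y) == brute_tomek_links(X.tolist(), y)

    def test_remove_tomek_drops_both_members(self):
        m = matrix([[0.0], [1.0]], ["approved", "problematic"])
        assert len(remove_tomek(m)) == 0

    def test_remove_tomek_one_sided_keeps_minority(self):
        m = matrix([[0.0], [1.0]], ["approved", "problematic"])
        out = remove_tomek(m, remove_both=False, minority="problematic")
        assert out.labels.tolist() == ["problematic"]

    def test_no_links_is_identity(self):
        m = matrix([[0, 0], [0.1, 0], [5, 5], [5.2, 5]],
                   ["approved", "approved", "problematic", "problematic"])
        out = remove_tomek(m)
        assert len(out) == 4

    def test_output_contains_no_input_link(self, rng):
        X = rng.uniform(size=(30, 2))
        y = rng.choice(["approved", "problematic"], size=30)
        m = matrix(X, y)
        out = remove_tomek(m)
        removed_ids = set(m.values.index) - set(out.values.index)
        for i, j in tomek_links(X, y):
            assert m.values.index[i] in removed_ids
            assert m.values.index[j] in removed_ids


class TestRemoveBorder:
    def test_minority_point_that_attracts_three_majority(self):
        # one problematic point is the NN of 3 approved points
        X = [[0.0, 0], [0.1, 0], [-0.1, 0], [0, 0.1], [5, 5]]
        y = ["problematic", "approved", "approved", "approved", "problematic"]
        out = remove_border(matrix(X, y), threshold=2)
        assert "D0" not in out.values.index
        assert "D4" in out.values.index

    def test_threshold_one_removes_any_opposite_nn_target(self):
        X = [[0.0], [0.4], [10.0]]
        y = ["problematic", "approved", "approved"]
        out = remove_border(matrix(X, y), threshold=1)
        # D0 and D1 are each other's NN with opposite classes -> both out
        assert set(out.values.index) == {"D2"}

    def test_matches_nn_count_oracle(self, rng):
        X = rng.uniform(size=(25, 2))
        y = rng.choice(["approved", "problematic"], size=25)
        # hand-count: how many opposite-class instances have each point as NN
        counts = np.zeros(25, dtype=int)
        for i in range(25):
            d = [np.inf if j == i else np.linalg.norm(X[i] - X[j]) for j in range(25)]
            j = int(np.argmin(d))
            if y[i] != y[j]:
                counts[j] += 1
        expected = {f"D{i}" for i in range(25) if counts[i] < 2}
        out = remove_border(matrix(X, y), threshold=2)
        assert set(out.values.index) == expected


class TestRemoveMisclassified:
    def test_separable_clusters_identity(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(5, 0.1, (15, 2))])
        y = ["approved"] * 15 + ["problematic"] * 15
        out = remove_misclassified(matrix(X, y), seed=0)
        assert len(out) == 30

    def test_planted_flip_removed(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (15, 2)), rng.normal(5, 0.05, (15, 2))])
        y = ["approved"] * 15 + ["problematic"] * 15
        y[0] = "problematic"  # mislabeled point deep inside the approved cluster
        out = remove_misclassified(matrix(X, y), seed=0)
        assert "D0" not in out.values.index
        assert len(out) == 29

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(size=(30, 3))
        y = rng.choice(["approved", "problematic"], size=30)
        a = remove_misclassified(matrix(X, y), seed=5)
        b = remove_misclassified(matrix(X, y), seed=5)
        assert a.values.index.tolist() == b.values.index.tolist()


class TestPreprocessCascade:
    def overlapping(self, rng, n_maj=50, n_min=10):
        X = np.vstack([rng.normal(0, 1.0, (n_maj, 3)), rng.normal(0.8, 1.0, (n_min, 3))])
        y = ["approved"] * n_maj + ["problematic"] * n_min
        return matrix(X, y)

    def test_all_steps_disabled_is_identity(self, rng):
        m = self.overlapping(rng)
        cfg = PreprocessConfig(smote_enabled=False, tomek_enabled=False,
                               border_enabled=False, misclassified_enabled=False)
        out, report = preprocess(m, cfg)
        assert out.values.equals(m.values)
        assert report["n_output"] == report["n_input"]

    def test_smote_count_before_cleaning(self, rng):
        m = self.overlapping(rng)
        cfg = PreprocessConfig(smote_percent=500, smote_k=8,
                               tomek_enabled=False, border_enabled=False,
                               misclassified_enabled=False, seed=0)
        out, report = preprocess(m, cfg)
        assert report["n_smote_synthetic"] == 50
        assert (out.labels == "problematic").sum() == 60

    def test_bookkeeping_sums(self, rng):
        m = self.overlapping(rng)
        out, r = preprocess(m, PreprocessConfig(seed=1))
        assert r["n_output"] == (
            r["n_input"] + r["n_smote_synthetic"] - r["n_tomek_removed"]
            - r["n_border_removed"] - r["n_misclassified_removed"]
        )
        assert len(out) == r["n_output"]

    def test_majority_instances_unchanged_by_smote(self, rng):
        m = self.overlapping(rng)
        cfg = PreprocessConfig(tomek_enabled=False, border_enabled=False,
                               misclassified_enabled=False, seed=0)
        out, _ = preprocess(m, cfg)
        maj_in = m.values[m.labels == "approved"]
        maj_out = out.values.loc[maj_in.index]
        assert maj_out.equals(maj_in)

    def test_minority_ratio_increases_on_overlap(self, rng):
        m = self.overlapping(rng)
        out, _ = preprocess(m, PreprocessConfig(seed=2))
        before = (m.labels == "problematic").mean()
        after = (out.labels == "problematic").mean()
        assert after > before

    def test_deterministic_under_seed(self, rng):
        m = self.overlapping(rng)
        a, _ = preprocess(m, PreprocessConfig(seed=3))
        b, _ = preprocess(m, PreprocessConfig(seed=3))
        assert a.values.equals(b.values)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(smote_percent=250)
        with pytest.raises(ValueError):
            PreprocessConfig(border_threshold=0)
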