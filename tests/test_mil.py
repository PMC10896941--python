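"""MIL label semantics, top-k selection, and planted-lesion recovery."""

import numpy as np
import pytest

from conftest import feature_mil_bags
from gasmil.mil import (Bag, MILConfig, MILError, PatchClassifier, PatchScore,
                        binarize_bag_label, load_classifier, save_classifier,
                        score_patches, select_top_k, slide_score,
                        train_patch_classifier)
from gasmil.staging import SlideGrades
from gasmil.tiling import TileRef


class TestBinarize:
    @pytest.mark.parametrize("grade,expected", [(0, 0), (1, 1), (2, 1), (3, 1)])
    def test_positive_iff_grade_above_zero(self, grade, expected):
        assert binarize_bag_label(grade) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(MILError):
            binarize_bag_label(4)


class TestSelectTopK:
    def score(self, vals_coords):
        return [PatchScore(TileRef("s", 0.5, r, c), p) for p, (r, c) in vals_coords]

    def test_descending_selection(self):
        scores = self.score([(0.9, (0, 0)), (0.1, (0, 1)), (0.5, (0, 2))])
        refs = select_top_k(scores, 2)
        assert [(r.row, r.col) for r in refs] == [(0, 0), (0, 2)]

    def test_k_larger_than_n_returns_all(self):
        scores = self.score([(0.2, (0, 0)), (0.8, (1, 1))])
        refs = select_top_k(scores, 10)
        assert [(r.row, r.col) for r in refs] == [(1, 1), (0, 0)]

    def test_ties_break_by_row_col(self):
        scores = self.score([(0.5, (0, 1)), (0.5, (0, 0))])
        refs = select_top_k(scores, 1)
        assert (refs[0].row, refs[0].col) == (0, 0)

    def test_invariant_to_input_order(self, rng):
        scores = self.score([(round(p, 1), (i // 4, i % 4))
                             for i, p in enumerate(rng.random(12))])
        shuffled = [scores[i] for i in rng.permutation(12)]
        assert select_top_k(scores, 5) == select_top_k(shuffled, 5)

    def test_empty_rejected(self):
        with pytest.raises(MILError):
            select_top_k([], 3)


@pytest.fixture(scope="module")
def trained_mil():
    bags, masks = feature_mil_bags()
    clf, log = train_patch_classifier(bags, MILConfig(feature="atrophy", epochs=25, seed=0))
    return bags, masks, clf, log


class TestTraining:
    def test_heldout_slide_auc_via_max_instance(self, trained_mil):
        from gasmil.metrics import auc
        bags, _, clf, _ = trained_mil
        test = [b for b in bags if b.split == "test"]
        y = [binarize_bag_label(b.labels.atrophy) for b in test]
        s = [slide_score(clf, b) for b in test]
        assert auc(y, s, n_boot=0).point >= 0.9

    def test_planted_instances_outrank_background(self, trained_mil):
        bags, masks, clf, _ = trained_mil
        ranks = []
        for b, m in zip(bags, masks):
            if b.split != "test" or not m.any():
                continue
            p = np.array([s.p_lesion for s in score_patches(clf, b)])
            ranks.append(p[m].mean() - p[~m].mean())
        assert np.mean(ranks) > 0.5

    def test_single_class_training_rejected(self, rng):
        bags = [Bag(f"b{i}", rng.normal(size=(4, 8)),
                    [TileRef(f"b{i}", 0.5, 0, j) for j in range(4)],
                    SlideGrades(0, 0, 0, 0), "train") for i in range(4)]
        with pytest.raises(MILError, match="positive and negative"):
            train_patch_classifier(bags, MILConfig(feature="atrophy", epochs=1))

    def test_epochs_zero_returns_untrained(self, rng):
        bags, _ = feature_mil_bags(n_bags=6, n_train=6, n_val=0)
        clf, log = train_patch_classifier(bags, MILConfig(feature="atrophy", epochs=0, seed=2))
        ref = PatchClassifier(bags[0].instances.shape[1], MILConfig(feature="atrophy", epochs=0, seed=2))
        assert log == []
        assert all(np.array_equal(clf.state_dict()[k], ref.state_dict()[k])
                   for k in clf.state_dict())


class TestScorePatches:
    def test_shape_range_and_duplication(self, trained_mil):
        bags, _, clf, _ = trained_mil
        b = bags[0]
        scores = score_patches(clf, b)
        assert len(scores) == len(b.instances)
        assert all(0 <= s.p_lesion <= 1 for s in scores)
        dup = Bag("d", np.vstack([b.instances[:1], b.instances[:1]]),
                  [TileRef("d", 0.5, 0, 0), TileRef("d", 0.5, 0, 1)],
                  b.labels, "test")
        s0, s1 = score_patches(clf, dup)
        assert s0.p_lesion == s1.p_lesion

    def test_no_cross_bag_leakage(self, trained_mil):
        bags, _, clf, _ = trained_mil
        alone = score_patches(clf, bags[0])
        again = score_patches(clf, bags[0])  # after scoring others
        score_patches(clf, bags[1])
        assert [s.p_lesion for s in alone] == [s.p_lesion for s in again]

    def test_dimension_mismatch_rejected(self, trained_mil):
        bags, _, clf, _ = trained_mil
        bad = Bag("x", np.zeros((2, 5)), [TileRef("x", 0.5, 0, j) for j in range(2)],
                  SlideGrades(0, 0, 1, 0), "test")
        with pytest.raises(MILError, match="dim"):
            score_patches(clf, bad)


def test_classifier_storage_roundtrip(trained_mil, tmp_path):
    bags, _, clf, _ = trained_mil
    save_classifier(tmp_path / "clf", clf)
    clf2 = load_classifier(tmp_path / "clf")
    p1 = clf.probs(bags[0].instances)
    p2 = clf2.probs(bags[0].instances)
    assert np.array_equal(p1, p2)
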