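import numpy as np
import pytest

from upffs.feature_eval import evaluate_feature
from upffs.selection import (
    apply_selection,
    cfs_select,
    svfs_select,
    unit_index_pairs,
    upffs_select,
)
from upffs.synth import PlantedDesign, generate_fc_dataset


@pytest.fixture(scope="module")
def mean_and_variance_planted():
    """Unit (0,1) differs between groups only in mean, (2,3) only in variance."""
    design = PlantedDesign(
        m=5, k=40, n_per_group=30,
        plant_map={(0, 1): (1, 1.0), (2, 3): (2, 1.0)}, seed=3,
    )
    ds = generate_fc_dataset(design)
    return ds.feature_tensors(), ds.labels


class TestUpffs:
    def test_fingerprint_assigns_planted_moments(self, mean_and_variance_planted):
        x, labels = mean_and_variance_planted
        fm, _ = upffs_select(x, labels, "ttest", 0.05)
        assert fm.best_order[0, 1] == 1
        assert fm.best_order[2, 3] == 2

    def test_matches_exhaustive_per_unit_loop(self, tensor_stack):
        x, labels = tensor_stack
        fm, sel = upffs_select(x, labels, "ttest", threshold=1.1)
        n, d, m, _ = x.shape
        assert len(sel.picks) == m * (m - 1) // 2  # before thresholding: all units
        for i in range(m):
            for j in range(i + 1, m):
                scores = [
                    evaluate_feature(x[:, dd, i, j], labels, "ttest").score
                    for dd in range(d)
                ]
                assert fm.best_order[i, j] == int(np.argmin(scores)) + 1
                assert fm.best_score[i, j] == pytest.approx(min(scores), abs=1e-12)

    def test_each_unit_at_most_once_after_thresholding(self, mean_and_variance_planted):
        x, labels = mean_and_variance_planted
        _, sel = upffs_select(x, labels, "ttest", 0.05)
        units = [(p.i, p.j) for p in sel.picks]
        assert len(units) == len(set(units))

    def test_ties_break_to_lowest_order(self):
        # duplicate the same feature at every order: all scores identical
        rng = np.random.default_rng(0)
        base = rng.standard_normal((12, 1, 3, 3))
        x = np.repeat(base, 4, axis=1)
        labels = np.tile([0, 1], 6)
        fm, _ = upffs_select(x, labels, "ttest", threshold=1.1)
        off = ~np.eye(3, dtype=bool)
        assert np.all(fm.best_order[off] == 1)

    def test_null_data_selects_near_nothing(self):
        ds = generate_fc_dataset(PlantedDesign(m=6, k=30, n_per_group=20, seed=9))
        x = ds.feature_tensors()
        _, sel = upffs_select(x, ds.labels, "ttest", 0.05)
        # 15 units, best-of-7 winners thresholded at 0.05: expect only a few
        assert len(sel.picks) <= 8

    def test_single_class_errors(self, tensor_stack):
        x, _ = tensor_stack
        with pytest.raises(ValueError, match="both classes"):
            upffs_select(x, np.ones(x.shape[0], dtype=int), "ttest", 0.05)


class TestSvfs:
    def test_planted_single_view_is_chosen(self):
        # only order-2 (variance) signal, planted at several units
        plant = {(0, 1): (2, 1.5), (0, 2): (2, 1.5), (1, 3): (2, 1.5), (2, 4): (2, 1.5)}
        ds = generate_fc_dataset(PlantedDesign(m=5, k=40, n_per_group=30, plant_map=plant, seed=5))
        sel = svfs_select(ds.feature_tensors(), ds.labels, "ttest", 0.05, seed=1)
        assert sel.svfs_chosen_view == 2
        assert all(p.d == 2 for p in sel.picks)

    def test_single_order_reduces_to_thresholded_evaluation(self, tensor_stack):
        x, labels = tensor_stack
        sel = svfs_select(x[:, :1], labels, "ttest", 0.5, seed=0)
        assert sel.svfs_chosen_view == 1
        expected = cfs_select(x[:, :1], labels, "ttest", 0.5)
        assert [(p.i, p.j, p.d) for p in sel.picks] == [
            (p.i, p.j, p.d) for p in expected.picks
        ]

    def test_deterministic_under_seed(self, mean_and_variance_planted):
        x, labels = mean_and_variance_planted
        a = svfs_select(x, labels, "ttest", 0.05, seed=4)
        b = svfs_select(x, labels, "ttest", 0.05, seed=4)
        assert a.svfs_chosen_view == b.svfs_chosen_view
        assert a.picks == b.picks


class TestCfs:
    def test_doubly_discriminative_unit_contributes_multiple_picks(self):
        # one unit with huge group differences in both its mean and its
        # variance feature: CFS keeps both, UPFFS keeps exactly one
        rng = np.random.default_rng(2)
        n, d, m = 60, 7, 5
        x = rng.standard_normal((n, d, m, m))
        x = 0.5 * (x + x.transpose(0, 1, 3, 2))
        labels = np.repeat([0, 1], n // 2)
        x[labels == 1, 0, 1, 2] += 3.0  # mean feature shifted
        x[labels == 1, 1, 1, 2] += 3.0  # variance feature shifted
        x[:, :, 2, 1] = x[:, :, 1, 2]
        cfs = cfs_select(x, labels, "ttest", 0.01)
        upf = upffs_select(x, labels, "ttest", 0.01)[1]
        cfs_at_unit = [p for p in cfs.picks if (p.i, p.j) == (1, 2)]
        upf_at_unit = [p for p in upf.picks if (p.i, p.j) == (1, 2)]
        assert len(cfs_at_unit) >= 2
        assert len(upf_at_unit) == 1

    def test_null_pick_count_near_binomial_expectation(self):
        ds = generate_fc_dataset(PlantedDesign(m=8, k=30, n_per_group=25, seed=13))
        x = ds.feature_tensors()
        n_candidates = 7 * 28
        picks = cfs_select(x, ds.labels, "ttest", 0.05).picks
        # binomial(196, ~0.05): mean ~10, allow a generous band
        assert len(picks) <= 30

    def test_vectorization_order_is_order_major(self, tensor_stack):
        x, labels = tensor_stack
        sel = cfs_select(x, labels, "ttest", threshold=1.1)  # keep everything
        m = x.shape[2]
        iu, ju = unit_index_pairs(m)
        expected = [
            (int(i), int(j), d + 1) for d in range(x.shape[1]) for i, j in zip(iu, ju)
        ]
        assert [(p.i, p.j, p.d) for p in sel.picks] == expected


class TestApplySelection:
    def test_training_application_reproduces_evaluated_values(self, tensor_stack):
        x, labels = tensor_stack
        _, sel = upffs_select(x, labels, "ttest", threshold=1.1)
        design = apply_selection(sel, x)
        assert design.shape == (x.shape[0], len(sel.picks))
        for col, p in enumerate(sel.picks):
            assert np.array_equal(design[:, col], x[:, p.d - 1, p.i, p.j])

    def test_empty_picks_error(self, tensor_stack):
        x, labels = tensor_stack
        sel = cfs_select(x, labels, "ttest", threshold=1e-12)
        assert len(sel.picks) == 0
        with pytest.raises(ValueError, match="no features selected"):
            apply_selection(sel, x)
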