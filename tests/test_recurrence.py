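"""Nine-class trinomial mixture: EM fit, allocation, exclusive selection."""

import numpy as np
import pandas as pd
import pytest

import cnatree as ct
from cnatree.recurrence import (allocate_bayes, collapse_states, component_table,
                                counts_from_matrix, fit_nine_class,
                                reference_class_probs, select_exclusive)


@pytest.fixture(scope="module")
def reference_fit():
    probs, labels = reference_class_probs()
    counts, classes = ct.simulate_band_counts(probs, n_bands=768, n_samples=42,
                                              seed=5)
    model = fit_nine_class(counts, n_starts=20, seed=0)
    return probs, labels, counts, classes, model


class TestCountsFromMatrix:
    def test_all_neutral(self):
        matrix = pd.DataFrame([["Neutral"] * 4] * 6,
                              columns=[f"b{i}" for i in range(4)])
        counts = counts_from_matrix(matrix)
        assert (counts["neutral"] == 6).all()
        assert (counts[["loss", "gain"]] == 0).all().all()

    def test_direct_count_and_cnloh_mapping(self):
        col = ["Loss"] * 29 + ["CNLOH"] * 3 + ["Neutral"] * 10
        matrix = pd.DataFrame({"b1": col})
        counts = counts_from_matrix(matrix)
        assert counts.loc["b1", "loss"] == 29
        assert counts.loc["b1", "neutral"] == 13     # CNLOH counted as Neutral
        assert counts.loc["b1", "gain"] == 0

    def test_missing_only_band_dropped(self):
        matrix = pd.DataFrame({"b1": ["Loss", "Neutral"],
                               "b2": ["Missing", "Missing"]})
        with pytest.warns(UserWarning):
            counts = counts_from_matrix(matrix)
        assert list(counts.index) == ["b1"]


class TestFitNineClass:
    def test_recovers_reference_probabilities(self, reference_fit):
        """Label-matched loss/gain probabilities within +-0.05 of truth."""
        probs, labels, _, _, model = reference_fit
        for lab, target in zip(labels, probs):
            k = model.component(*lab)
            assert model.theta[k, 0] == pytest.approx(target[0], abs=0.05)
            assert model.theta[k, 2] == pytest.approx(target[2], abs=0.05)

    def test_grid_pattern_of_labels(self, reference_fit):
        """Loss grows along loss levels; gain grows along gain levels."""
        _, _, _, _, model = reference_fit
        for gain_level in ("low", "medium", "high"):
            lam = [model.theta[model.component(l, gain_level), 0]
                   for l in ("low", "medium", "high")]
            assert lam[0] < lam[1] < lam[2]
        for loss_level in ("low", "medium", "high"):
            gam = [model.theta[model.component(loss_level, g), 2]
                   for g in ("low", "medium", "high")]
            assert gam[0] < gam[1] < gam[2]

    def test_loglik_non_decreasing_in_iterations(self):
        probs, _ = reference_class_probs()
        counts, _ = ct.simulate_band_counts(probs, n_bands=120, n_samples=42,
                                            seed=1)
        short = fit_nine_class(counts, n_starts=1, seed=7, max_iter=3)
        long = fit_nine_class(counts, n_starts=1, seed=7, max_iter=400)
        assert long.loglik >= short.loglik - 1e-9

    def test_degenerate_identical_counts(self):
        counts = np.tile([5, 30, 7], (20, 1))
        model = fit_nine_class(counts, n_starts=3, seed=0)
        # one component's expected cell probabilities absorb the common row
        _, post = allocate_bayes(model, counts)
        k = int(np.argmax(post[0]))
        assert model.theta[k] == pytest.approx(np.array([5, 30, 7]) / 42, abs=0.02)

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError):
            fit_nine_class(np.tile([1, 40, 1], (5, 1)))


class TestAllocation:
    def test_posteriors_sum_to_one(self, reference_fit):
        _, _, counts, _, model = reference_fit
        _, post = allocate_bayes(model, counts)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_map_at_component_expectation(self, reference_fit):
        """A band with counts at a well-separated component's mean is MAP there."""
        probs, labels, _, _, model = reference_fit
        k_del = model.component("high", "low")
        x = np.round(model.theta[k_del] * 42).astype(int)
        x[1] = 42 - x[0] - x[2]
        alloc, _ = allocate_bayes(model, x[None, :])
        assert alloc[0] == k_del

    def test_equal_likelihood_tie_breaks_low_index(self):
        model = ct.NineClassModel(
            pi=np.full(9, 1 / 9), theta=np.tile([0.2, 0.6, 0.2], (9, 1)),
            labels=[("low", "low")] * 9, loglik=0.0, n_iter=1, converged=True)
        alloc, post = allocate_bayes(model, np.array([[3, 30, 9]]))
        assert alloc[0] == 0
        assert np.allclose(post, 1 / 9)

    def test_allocation_equivariant_under_band_permutation(self, reference_fit):
        _, _, counts, _, model = reference_fit
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(counts))
        alloc, _ = allocate_bayes(model, counts)
        alloc_p, _ = allocate_bayes(model, counts[perm])
        assert (alloc_p == alloc[perm]).all()


class TestExclusive:
    def test_reference_components_define_the_sets(self, reference_fit):
        probs, labels, counts, classes, model = reference_fit
        alloc, _ = allocate_bayes(model, counts)
        excl = select_exclusive(model, alloc)
        assert not excl.deleted & excl.amplified
        true_del = set(np.flatnonzero(classes == labels.index(("high", "low"))))
        true_amp = set(np.flatnonzero(classes == labels.index(("low", "high"))))
        # recovered sets agree with the generating classes for most bands
        assert len(excl.deleted & true_del) / len(true_del) > 0.7
        assert len(excl.amplified & true_amp) / len(true_amp) > 0.7

    def test_all_neutral_cohort_has_empty_sets(self):
        matrix = pd.DataFrame([["Neutral"] * 30] * 42,
                              columns=[f"b{i}" for i in range(30)])
        counts = counts_from_matrix(matrix)
        model = fit_nine_class(counts, n_starts=3, seed=0)
        alloc, _ = allocate_bayes(model, counts)
        excl = select_exclusive(model, alloc, counts.index)
        assert excl.deleted == set() and excl.amplified == set()

    def test_recurrent_loss_band_lands_in_deleted_set(self):
        rng = np.random.default_rng(0)
        probs, labels = reference_class_probs()
        counts, classes = ct.simulate_band_counts(probs, n_bands=200,
                                                  n_samples=42, seed=2)
        counts = np.vstack([counts, [30, 12, 0]])   # 70% loss, never gain
        model = fit_nine_class(counts, n_starts=20, seed=0)
        alloc, _ = allocate_bayes(model, counts)
        excl = select_exclusive(model, alloc)
        assert 200 in excl.deleted


class TestCollapse:
    def test_rule_application(self):
        matrix = pd.DataFrame({
            "amp": ["Loss", "Neutral", "Gain", "Gain"],
            "del": ["Loss", "Loss", "Gain", "Neutral"],
            "other": ["Loss", "Gain", "Neutral", "CNLOH"],
        })
        excl = ct.ExclusiveSets(deleted={"del"}, amplified={"amp"})
        out = collapse_states(matrix, excl)
        assert list(out["amp"]) == ["Neutral", "Neutral", "Gain", "Gain"]
        assert list(out["del"]) == ["Loss", "Loss", "Neutral", "Neutral"]
        assert list(out["other"]) == list(matrix["other"])


def test_component_table_shape(reference_fit):
    _, _, _, _, model = reference_fit
    table = component_table(model)
    assert len(table) == 9
    assert np.allclose(table[["p_loss", "p_neutral", "p_gain"]].sum(axis=1), 1.0)
    assert table["weight"].sum() == pytest.approx(1.0)
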