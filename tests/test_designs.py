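import numpy as np
import pytest

from topostats.data_io import ErpDataset
from topostats.designs import (BetweenDesign, WithinDesign, cell_means,
                               count_relabelings, draw_relabelings,
                               enumerate_effects, enumerate_relabelings,
                               shuffle_labels)
from topostats.simulate import (GenerativeSpec, SourceEffect, boxcar,
                                generate, random_topography)


class TestWithinDesign:
    def test_orthogonality_enforced(self):
        with pytest.raises(ValueError, match="orthogonal"):
            WithinDesign(((0, 0), (0, 1), (1, 0)))  # missing (1,1)

    def test_exclusion_that_breaks_crossing_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            WithinDesign(((0, 0), (0, 1), (1, 0), (None, None), (1, 1),
                          (1, 1)))  # cell (1,1) now doubled, others single

    def test_partial_level_assignment_rejected(self):
        with pytest.raises(ValueError, match="every factor"):
            WithinDesign(((0, 0), (0, None)))

    def test_three_factors_rejected(self):
        with pytest.raises(ValueError, match="two"):
            WithinDesign(((0, 0, 0), (1, 1, 1)))

    def test_excluded_conditions_tracked(self):
        w = WithinDesign(((0,), (1,), (None,)))
        assert w.included.tolist() == [0, 1]


class TestBetweenDesign:
    def test_continuous_needs_spread(self):
        with pytest.raises(ValueError, match="distinct"):
            BetweenDesign("continuous", (1.0, 1.0, 1.0))

    def test_use_flags_can_rescue_validity(self):
        b = BetweenDesign("continuous", (1.0, 2.0, 3.0),
                          use=(False, True, True))
        assert b.used.tolist() == [1, 2]

    def test_group_codes_are_contiguous(self):
        b = BetweenDesign("categorical", (5, 9, 5, 9))
        assert b.group_codes().tolist() == [0, 1, 0, 1]


class TestEnumerateEffects:
    def test_counts(self, within_2x2, within_1f, groups_2):
        assert [e.id for e in enumerate_effects(within_2x2, groups_2)] == \
            ["A", "B", "AxB", "G", "GxA", "GxB", "GxAxB"]
        assert [e.id for e in enumerate_effects(within_2x2)] == \
            ["A", "B", "AxB"]
        assert [e.id for e in enumerate_effects(within_1f)] == ["A"]

    def test_covariate_analogues(self, within_2x2):
        cov = BetweenDesign("continuous", tuple(range(6)), name="improvement")
        ids = [e.id for e in enumerate_effects(within_2x2, cov)]
        assert ids == ["A", "B", "AxB", "COV", "COVxA", "COVxB", "COVxAxB"]
        eff = enumerate_effects(within_2x2, cov)[4]
        assert eff.is_covariate and eff.name == "improvement x day"

    def test_pure_function_of_designs(self, within_2x2, groups_2):
        assert enumerate_effects(within_2x2, groups_2) == \
            enumerate_effects(within_2x2, groups_2)


class TestCellMeans:
    def test_copies_give_identical_means(self, within_2x2):
        m = np.arange(6.0) - np.arange(6.0).mean()
        data = np.tile(m, (4, 4, 3, 1))
        ds = ErpDataset(data, average_referenced=True)
        for eff in enumerate_effects(within_2x2):
            cms = cell_means(ds, within_2x2, None, eff, 1)
            if not eff.is_interaction:
                for cm in cms:
                    assert cm == pytest.approx(m)
            else:  # centered: all zero
                for cm in cms:
                    assert cm == pytest.approx(np.zeros(6), abs=1e-12)

    def test_main_effect_marginalizes_other_factor(self, within_2x2, rng):
        data = rng.standard_normal((5, 4, 2, 6))
        data -= data.mean(axis=3, keepdims=True)
        ds = ErpDataset(data, average_referenced=True)
        effA = enumerate_effects(within_2x2)[0]
        cms = cell_means(ds, within_2x2, None, effA, 0)
        # A level 0 = conditions 0,1 averaged over subjects and B levels
        expected = data[:, :2, 0, :].mean(axis=(0, 1))
        assert cms[0] == pytest.approx(expected)
        assert len(cms) == 2

    def test_additive_data_has_zero_interaction(self, within_2x2):
        # pure main effects of A and B, no noise -> interaction residual 0
        rng = np.random.default_rng(7)
        spec = GenerativeSpec(
            n_subjects=6, n_time=8, n_sensors=10, noise_sd=0.0,
            sources=(
                SourceEffect(random_topography(10, rng), boxcar(8, 0, 8),
                             condition_weights=np.array([1, 1, -1, -1.0])),
                SourceEffect(random_topography(10, rng), boxcar(8, 0, 8),
                             condition_weights=np.array([1, -1, 1, -1.0])),
            ))
        ds, _ = generate(spec)
        effAB = enumerate_effects(within_2x2)[2]
        for cm in cell_means(ds, within_2x2, None, effAB, 4):
            assert cm == pytest.approx(np.zeros(10), abs=1e-10)

    def test_group_effect_cell_count(self, within_2x2, groups_2,
                                     small_null_dataset):
        effG = enumerate_effects(within_2x2, groups_2)[3]
        cms = cell_means(small_null_dataset, within_2x2, groups_2, effG, 0)
        assert len(cms) == 2


class TestShuffling:
    def test_two_level_main_effect_has_2_pow_n_relabelings(self, within_2x2):
        effA = enumerate_effects(within_2x2)[0]
        rng = np.random.default_rng(0)
        seen = {tuple(map(tuple, shuffle_labels(
            within_2x2, None, effA, rng, n_subjects=3).cond_source))
            for _ in range(500)}
        assert len(seen) == 8
        assert count_relabelings(within_2x2, None, effA, 3) == 8

    def test_a_labels_swap_jointly_across_b(self, within_2x2):
        effA = enumerate_effects(within_2x2)[0]
        rng = np.random.default_rng(1)
        for _ in range(20):
            rel = shuffle_labels(within_2x2, None, effA, rng, n_subjects=2)
            for row in rel.cond_source:
                assert tuple(row) in ((0, 1, 2, 3), (2, 3, 0, 1))

    def test_identity_occurs(self, within_2x2):
        effA = enumerate_effects(within_2x2)[0]
        rng = np.random.default_rng(2)
        idt = (0, 1, 2, 3)
        assert any(tuple(shuffle_labels(within_2x2, None, effA, rng,
                                        n_subjects=1).cond_source[0]) == idt
                   for _ in range(100))

    def test_between_shuffle_leaves_conditions_alone(self, within_2x2,
                                                     groups_2):
        effG = enumerate_effects(within_2x2, groups_2)[3]
        rng = np.random.default_rng(3)
        rel = shuffle_labels(within_2x2, groups_2, effG, rng, n_subjects=12)
        assert np.array_equal(rel.cond_source,
                              np.tile(np.arange(4), (12, 1)))
        assert sorted(rel.subject_source) == list(range(12))

    def test_relabeling_permutes_within_each_subject(self, within_2x2):
        # the multiset of condition indices per subject is invariant
        effAB = enumerate_effects(within_2x2)[2]
        rng = np.random.default_rng(4)
        cond, _ = draw_relabelings(within_2x2, None, effAB, 7, rng, n=50)
        assert np.all(np.sort(cond, axis=-1) == np.arange(4))

    def test_exhaustive_enumeration_is_complete_and_distinct(self,
                                                             within_1f):
        effA = enumerate_effects(within_1f)[0]
        rels = list(enumerate_relabelings(within_1f, None, effA, 3))
        assert len(rels) == 8
        assert len({tuple(map(tuple, r.cond_source)) for r in rels}) == 8

    def test_shuffled_cell_means_converge_to_grand_mean(self, within_2x2,
                                                        small_null_dataset):
        # law of large numbers: averaging cell means over many shuffles
        # recovers the grand mean within 3 standard errors
        ds = small_null_dataset
        effA = enumerate_effects(within_2x2)[0]
        rng = np.random.default_rng(5)
        t = 10
        X = ds.data[:, :, t, :]  # (S, C, J)
        n = 4000
        cond, _ = draw_relabelings(within_2x2, None, effA, ds.n_subjects,
                                   rng, n=n)
        # cell 0 of effect A = labels {0, 1}; gather the shuffled means
        shuffled = X[np.arange(ds.n_subjects)[:, None, None],
                     cond.transpose(1, 0, 2)]  # (S, n, C, J)
        cell0 = shuffled[:, :, :2, :].mean(axis=(0, 2))  # (n, J)
        grand = X.mean(axis=(0, 1))
        se = cell0.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(cell0.mean(axis=0) - grand) < 3 * se + 1e-12)
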