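import math

import numpy as np
import pytest

from oracles import brute_force_beliefs
from subcell.evclassifier import (
    MassAssignment,
    ReferenceLibrary,
    SpaceParams,
    combine_masses,
    etknn_vote,
    fit_gammas,
    neighbor_masses,
    read_library,
    space_distance,
    write_library,
)


class TestSpaceDistance:
    def test_identical_vectors_are_at_zero(self):
        assert space_distance({1, 2}, {1, 2}, "go") == 0.0
        assert space_distance(np.ones(5), np.ones(5), "psepssm") == 0.0

    def test_disjoint_binary_sets_are_at_one(self):
        assert space_distance({1, 2}, {3, 4}, "fund") == 1.0

    def test_jaccard_worked_example(self):
        assert space_distance({1, 2, 3}, {2, 3, 4}, "go") == pytest.approx(0.5)

    def test_both_empty_sets_are_at_zero(self):
        assert space_distance(set(), set(), "go") == 0.0

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            space_distance(np.ones(5), np.ones(6), "psepssm")

    def test_combined_space_mixes_normalized_blocks(self):
        params = SpaceParams(weight=0.5, pse_scale=2.0)
        a = ({1, 2}, np.zeros(3))
        b = ({3, 4}, np.array([2.0, 0.0, 0.0]))
        # 0.5 * 1 (disjoint) + 0.5 * (2 / 2)
        assert space_distance(a, b, "fund+psepssm", params) == pytest.approx(1.0)


class TestMasses:
    def test_zero_distance_mass_is_alpha(self):
        (ma,) = neighbor_masses([(0.0, 1)], alpha=0.95, gammas={1: 3.0})
        assert ma.singleton_masses[1] == pytest.approx(0.95)

    def test_large_distance_mass_vanishes(self):
        (ma,) = neighbor_masses([(100.0, 1)], alpha=0.95, gammas={1: 1.0})
        assert ma.singleton_masses[1] == pytest.approx(0.0, abs=1e-12)
        assert ma.frame_mass == pytest.approx(1.0, abs=1e-12)

    def test_worked_mass_value(self):
        (ma,) = neighbor_masses([(1.0, 2)], alpha=0.95, gammas={2: 1.0})
        assert ma.singleton_masses[2] == pytest.approx(0.95 * math.exp(-1.0))
        assert ma.singleton_masses[2] == pytest.approx(0.3495, abs=1e-4)

    def test_non_finite_distance_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            neighbor_masses([(math.nan, 1)], 0.95, {1: 1.0})

    def test_mass_assignment_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MassAssignment({1: 0.5}, 0.6)


class TestCombineMasses:
    def test_single_assignment_is_identity(self):
        beliefs = combine_masses([MassAssignment({2: 0.7}, 0.3)])
        assert beliefs[2] == pytest.approx(0.7)

    def test_agreeing_assignments_reinforce(self):
        beliefs = combine_masses(
            [MassAssignment({1: 0.5}, 0.5), MassAssignment({1: 0.6}, 0.4)]
        )
        assert beliefs[1] >= 0.6

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_brute_force_enumeration(self, rng, k):
        for _ in range(50):
            pairs = [
                (int(rng.integers(1, 4)), float(rng.uniform(0.0, 0.95)))
                for _ in range(k)
            ]
            ours = combine_masses(
                [MassAssignment({c: m}, 1.0 - m) for c, m in pairs]
            )
            expected = brute_force_beliefs(pairs)
            for cls, b in expected.items():
                assert ours[cls] == pytest.approx(b, abs=1e-10)


def _euclid_library(points, labels):
    return ReferenceLibrary(
        [np.asarray(p, dtype=float) for p in points],
        np.asarray(labels, dtype=int),
        [f"s{i}" for i in range(len(points))],
        "psepssm",
    )


class TestVote:
    def test_k1_returns_nearest_label(self):
        lib = _euclid_library([[0.0], [5.0]], [1, 2])
        assert etknn_vote(np.array([0.4]), lib, 1) == 1
        assert etknn_vote(np.array([4.9]), lib, 1) == 2

    def test_unanimous_neighborhood(self):
        lib = _euclid_library([[0.0], [0.1], [0.2], [9.0]], [2, 2, 2, 1])
        assert etknn_vote(np.array([0.0]), lib, 3) == 2

    def test_three_neighbor_case_matches_mass_oracle(self):
        lib = _euclid_library([[0.1], [0.2], [0.9]], [1, 2, 2])
        gammas = fit_gammas(lib)
        query = np.array([0.0])
        dists = lib.distances_to(query)
        pairs = [
            (int(lib.labels[i]), 0.95 * math.exp(-gammas[int(lib.labels[i])] * dists[i] ** 2))
            for i in range(3)
        ]
        expected = brute_force_beliefs(pairs)
        winner = min(expected.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        assert etknn_vote(query, lib, 3, gammas=gammas) == winner

    def test_permutation_of_library_preserves_vote(self, rng):
        points = rng.normal(size=(12, 3))
        labels = rng.integers(1, 4, size=12)
        lib = _euclid_library(points, labels)
        gammas = fit_gammas(lib)
        perm = rng.permutation(12)
        lib2 = _euclid_library(points[perm], labels[perm])
        query = rng.normal(size=3)
        assert etknn_vote(query, lib, 5, gammas=gammas) == etknn_vote(
            query, lib2, 5, gammas=gammas
        )

    def test_high_alpha_equals_majority_knn_on_separated_clusters(self, rng):
        pts = np.vstack(
            [rng.normal(0.0, 0.1, size=(10, 2)), rng.normal(8.0, 0.1, size=(10, 2))]
        )
        labels = np.array([1] * 10 + [2] * 10)
        lib = _euclid_library(pts, labels)
        gammas = {1: 1.0, 2: 1.0}
        for query, want in [(np.array([0.1, 0.0]), 1), (np.array([7.9, 8.1]), 2)]:
            assert (
                etknn_vote(query, lib, 7, alpha=0.999, gammas=gammas) == want
            )

    def test_empty_library_and_bad_k_rejected(self):
        lib = _euclid_library([[0.0]], [1])
        with pytest.raises(ValueError):
            etknn_vote(np.array([0.0]), lib, 2)


class TestFitGammas:
    def test_doubling_distances_quarters_gammas(self, rng):
        points = rng.normal(size=(10, 4))
        labels = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        g1 = fit_gammas(_euclid_library(points, labels))
        g2 = fit_gammas(_euclid_library(points * 2.0, labels))
        for cls in (1, 2):
            assert g2[cls] == pytest.approx(g1[cls] / 4.0)

    def test_duplicate_points_fall_back_to_global_rule(self):
        lib = _euclid_library([[0.0], [0.0], [1.0], [3.0]], [1, 1, 2, 2])
        gammas = fit_gammas(lib)
        # class 2's NN squared distance is 4; class 1 is degenerate -> global
        assert gammas[2] == pytest.approx(0.25)
        assert gammas[1] == pytest.approx(0.25)

    def test_single_class_library_fits(self):
        lib = _euclid_library([[0.0], [1.0], [2.0]], [3, 3, 3])
        gammas = fit_gammas(lib)
        assert gammas[3] > 0
        assert etknn_vote(np.array([0.5]), lib, 2, gammas=gammas) == 3

    def test_grid_refinement_returns_positive_scales(self, rng):
        points = rng.normal(size=(12, 2))
        labels = rng.integers(1, 3, size=12)
        gammas = fit_gammas(_euclid_library(points, labels), refine=True)
        assert all(g > 0 for g in gammas.values())


class TestSerialization:
    @pytest.mark.parametrize("space", ["go", "psepssm", "fund+psepssm"])
    def test_round_trip(self, tmp_path, rng, space):
        if space == "go":
            feats = [frozenset({1, 5}), frozenset({2}), frozenset()]
        elif space == "psepssm":
            feats = [rng.normal(size=4) for _ in range(3)]
        else:
            feats = [
                (frozenset({1}), rng.normal(size=4)) for _ in range(3)
            ]
        lib = ReferenceLibrary(
            feats, np.array([1, 2, 1]), ["a", "b", "c"], space,
            dimension=100, params=SpaceParams(0.4, 2.5),
        )
        path = tmp_path / "lib.tsv"
        write_library(lib, path)
        back = read_library(path)
        assert back.space_tag == lib.space_tag
        assert back.labels.tolist() == lib.labels.tolist()
        assert back.source_ids == lib.source_ids
        assert back.params == lib.params
        for f1, f2 in zip(lib.features, back.features):
            if space == "go":
                assert f1 == f2
            elif space == "psepssm":
                np.testing.assert_allclose(f1, f2, atol=1e-10)
            else:
                assert f1[0] == f2[0]
                np.testing.assert_allclose(f1[1], f2[1], atol=1e-10)
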