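"""Category-structure fixtures and trial protocols."""

import itertools

import numpy as np
import pytest

from refreshcat.distributions import bell_number, canonical_partition
from refreshcat.tasks import (
    biconditional_structure,
    classify_balanced_split,
    condensation_filtration_structure,
    discrimination_grid,
    free_classification_structure,
    garner_tasks,
    generate_cluster_training,
    partition_type,
    shj_structure,
    shj_truth_tables,
    trial_stream,
)


class TestSHJ:
    def test_all_balanced_splits_fall_into_six_types(self):
        """The 70 balanced 4/4 splits of the cube form exactly six classes."""
        cube = list(itertools.product((0, 1), repeat=3))
        seen = {}
        for combo in itertools.combinations(cube, 4):
            t = classify_balanced_split(np.array(combo))
            seen.setdefault(t, 0)
            seen[t] += 1
        assert set(seen) == {"I", "II", "III", "IV", "V", "VI"}
        assert sum(seen.values()) == 70
        # each unordered split is counted once per labeling of category A
        assert seen["I"] == 6 and seen["II"] == 6 and seen["VI"] == 2

    def test_truth_tables_have_their_own_type(self):
        for tp, table in shj_truth_tables().items():
            assert classify_balanced_split(table) == tp

    @pytest.mark.parametrize("tp", ["I", "II", "III", "IV", "V", "VI"])
    def test_labels_balanced(self, tp):
        st = shj_structure(tp)
        assert st.labels.sum() == 4

    def test_type_i_depends_on_first_dimension_only(self):
        st = shj_structure("I")
        for (s, lab) in zip(st.stimuli, st.labels):
            assert lab == int(s[0] != 0)

    def test_type_ii_is_exclusive_or(self):
        st = shj_structure("II")
        for (s, lab) in zip(st.stimuli, st.labels):
            assert (int(s[0]) == int(s[1])) == (lab == 0)

    def test_type_vi_is_parity(self):
        st = shj_structure("VI")
        labels = {tuple(s): lab for s, lab in zip(st.stimuli, st.labels)}
        for s, lab in labels.items():
            for d in range(3):
                flipped = list(s)
                flipped[d] = 1.0 - flipped[d]
                assert labels[tuple(flipped)] != lab

    def test_mapping_permutes_relevant_dimension(self):
        st = shj_structure("I", mapping=(2, 0, 1))
        # abstract dimension 0 now rides on stimulus dimension 2
        for (s, lab) in zip(st.stimuli, st.labels):
            assert lab == int(s[2] != 0)

    def test_block_has_two_copies_of_each_stimulus(self):
        st = shj_structure("IV")
        assert len(st.block) == 16
        assert sorted(st.block) == sorted(list(range(8)) * 2)


class TestCondensationFiltration:
    def test_shared_coordinates(self):
        sts = [condensation_filtration_structure(c)
               for c in ("filtration_dim1", "condensation_A")]
        np.testing.assert_array_equal(sts[0].stimuli, sts[1].stimuli)

    def test_balanced_labels_all_conditions(self):
        for c in ("filtration_dim1", "filtration_dim2",
                  "condensation_A", "condensation_B"):
            st = condensation_filtration_structure(c)
            assert st.labels.sum() == 4

    def test_filtration_boundary_axis_parallel(self):
        st = condensation_filtration_structure("filtration_dim1")
        xs0 = st.stimuli[st.labels == 0][:, 0]
        xs1 = st.stimuli[st.labels == 1][:, 0]
        assert xs0.max() < xs1.min()

    def test_condensation_categories_further_apart(self):
        def sep(cond):
            st = condensation_filtration_structure(cond)
            m0 = st.stimuli[st.labels == 0].mean(axis=0)
            m1 = st.stimuli[st.labels == 1].mean(axis=0)
            return np.linalg.norm(m0 - m1)

        assert sep("condensation_A") > sep("filtration_dim1")
        assert sep("condensation_B") > sep("filtration_dim2")


class TestBiconditional:
    def test_diagonal_corners_share_labels(self):
        st = biconditional_structure("separable_pairing")
        varying = st.meta["varying_dims"]
        pts = st.stimuli[:, list(varying)]
        for a, b in itertools.combinations(range(4), 2):
            if np.isclose(np.abs(pts[a] - pts[b]).sum(), 2.0):  # diagonal
                assert st.labels[a] == st.labels[b]

    def test_unused_dimension_at_zero(self):
        st = biconditional_structure("integral_pairing")
        assert (st.stimuli[:, 2] == 0).all()

    def test_matches_upper_half_of_type_ii(self):
        """Exclusive-or labels on the varying pair, as in the Type II problem."""
        st = biconditional_structure("integral_pairing")
        for s, lab in zip(st.stimuli, st.labels):
            assert lab == int(s[0]) ^ int(s[1])


class TestFreeClassification:
    def test_critical_partitions_are_three_three(self):
        _, crit = free_classification_structure()
        assert len(crit) == 3
        for p in crit.values():
            sizes = np.bincount(np.asarray(p))
            assert sorted(sizes) == [3, 3]

    def test_identity_partition_groups_exact_matches(self):
        st, crit = free_classification_structure()
        p = np.asarray(crit["one_dimensional_identity"])
        for g in (0, 1):
            vals = st.stimuli[p == g][:, 0]
            assert np.allclose(vals, vals[0])

    def test_other_partitions_count(self):
        _, crit = free_classification_structure()
        others = bell_number(6) - len(set(crit.values()))
        assert others == 200
        assert partition_type((0, 1, 2, 3, 4, 5), crit) == "other"
        assert partition_type((1, 1, 1, 0, 0, 0),
                              crit) == "one_dimensional_identity"


class TestDimensionalLearningTasks:
    def test_grid_neighbor_pairs(self):
        task = discrimination_grid()
        assert len(task["neighbor_pairs"]) == 24
        assert sum(1 for *_, d in task["neighbor_pairs"] if d == 0) == 12

    def test_grid_quadrant_labels(self):
        task = discrimination_grid()
        st = task["train_1d_dim1"]
        for (x, y), lab in zip(task["grid"], st.labels):
            assert lab == int(x >= task["median"])
        assert len(set(task["train_2d"].labels.tolist())) == 4

    def test_garner_target_dimension_values_shared(self):
        tasks = garner_tasks(train_spacing=1.0)
        filt = sorted(set(tasks["filtering"].stimuli[:, 0]))
        base = sorted(set(np.concatenate([
            tasks["baseline_low"].stimuli[:, 0],
            tasks["baseline_high"].stimuli[:, 0]])))
        assert filt == base

    def test_garner_test_spacing_doubled(self):
        tasks = garner_tasks(train_spacing=1.0)
        train_span = np.ptp(tasks["training"].stimuli[:, 0])
        test_span = np.ptp(tasks["filtering"].stimuli[:, 0])
        assert test_span == pytest.approx(2 * train_span)

    def test_garner_blocks_equal_length(self):
        tasks = garner_tasks()
        assert len(tasks["filtering"].block) == len(tasks["baseline_low"].block)


class TestSyntheticTraining:
    def test_preset_shape_and_reproducibility(self):
        a = generate_cluster_training(preset="six_axis_aligned", seed=3)
        b = generate_cluster_training(preset="six_axis_aligned", seed=3)
        assert a.n == 180
        np.testing.assert_array_equal(a.points, b.points)
        assert len(set(a.contexts.tolist())) == 6

    def test_sample_covariance_near_generator(self):
        ts = generate_cluster_training(preset="six_axis_aligned", seed=5)
        for k in range(6):
            pts = ts.points[ts.cluster_ids == k]
            emp = np.cov(pts.T)
            gen = ts.covariances[k]
            for d in range(2):
                assert abs(emp[d, d] - gen[d, d]) / gen[d, d] < 0.6

    def test_rotated_preset_is_rotation_of_covariances(self):
        rot = generate_cluster_training(preset="six_rotated", seed=3)
        t = np.deg2rad(45.0)
        r = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        plain = generate_cluster_training(preset="six_axis_aligned", seed=3)
        for k in range(6):
            np.testing.assert_allclose(
                rot.covariances[k], r @ plain.covariances[k] @ r.T, atol=1e-12)

    def test_fixture_table_round_trip(self):
        from refreshcat.tasks import structure_from_table, structure_to_table

        st = shj_structure("III")
        table = structure_to_table(st)
        again = structure_from_table(table, name=st.name, block=st.block,
                                     n_blocks=st.n_blocks)
        np.testing.assert_array_equal(again.stimuli, st.stimuli)
        np.testing.assert_array_equal(again.labels, st.labels)
        assert again.block == st.block

    def test_trial_stream_deterministic(self):
        st = condensation_filtration_structure("filtration_dim1", n_blocks=3)
        a = trial_stream(st, 9)
        b = trial_stream(st, 9)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 24
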